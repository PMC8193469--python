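"""PSSM binding-site prediction with a Markov-order-1 background.

The scanner mirrors matrix-scan-style site prediction: candidate sites are
scored by the natural-log odds of the window under the motif versus under an
order-1 Markov background (the background likelihood of each base is
conditioned on the preceding base), and a site is reported when its score
passes a raw lower threshold (default 1) *and* its background p-value passes
an upper threshold (default 1e-5).  P-values are exact up to score
discretization, from a dynamic programme over (position, previous base,
score bin).

Also houses the hypergeometric tail test and the random-gene-group
randomization used to assess interaction-matrix enrichment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G


class MotifError(ValueError):
    pass


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to 0..3 (A,C,G,T); other letters become -1."""
    table = np.full(256, -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(arr: np.ndarray) -> str:
    return "".join(BASES[i] if i >= 0 else "N" for i in arr)


def reverse_complement(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    ok = out >= 0
    out[ok] = _COMPLEMENT[out[ok]]
    return out


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkovBackground:
    """Order-1 Markov sequence model (initial distribution + 4x4 transitions)."""

    initial: np.ndarray
    transition: np.ndarray
    order: int = 1

    def __post_init__(self):
        initial = np.asarray(self.initial, dtype=float)
        transition = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "initial", initial)
        object.__setattr__(self, "transition", transition)
        if initial.shape != (4,) or transition.shape != (4, 4):
            raise MotifError("background needs a length-4 initial and 4x4 transition")
        if abs(initial.sum() - 1.0) > 1e-12:
            raise MotifError("initial distribution must sum to 1")
        if np.any(np.abs(transition.sum(axis=1) - 1.0) > 1e-12):
            raise MotifError("transition rows must sum to 1")
        if np.any(initial <= 0) or np.any(transition <= 0):
            raise MotifError("background probabilities must be > 0 (smooth the counts)")

    @classmethod
    def uniform(cls) -> "MarkovBackground":
        return cls(np.full(4, 0.25), np.full((4, 4), 0.25))

    @classmethod
    def from_sequences(cls, sequences, pseudocount: float = 1.0) -> "MarkovBackground":
        """Estimate from sequences by dinucleotide counting, add-one style smoothing."""
        mono = np.zeros(4)
        dinu = np.zeros((4, 4))
        for seq in sequences:
            arr = seq if isinstance(seq, np.ndarray) else encode_sequence(seq)
            ok = arr >= 0
            np.add.at(mono, arr[ok], 1)
            a, b = arr[:-1], arr[1:]
            pair_ok = (a >= 0) & (b >= 0)
            np.add.at(dinu, (a[pair_ok], b[pair_ok]), 1)
        mono = mono + pseudocount
        dinu = dinu + pseudocount
        return cls(mono / mono.sum(), dinu / dinu.sum(axis=1, keepdims=True))

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the transition matrix."""
        vals, vecs = np.linalg.eig(self.transition.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()

    def sample(self, length: int, rng: np.random.Generator) -> np.ndarray:
        """Draw one sequence of the given length (encoded 0..3)."""
        out = np.empty(length, dtype=np.int64)
        u = rng.random(length)
        cum_init = np.cumsum(self.initial)
        cum_trans = np.cumsum(self.transition, axis=1)
        out[0] = np.searchsorted(cum_init, u[0])
        for i in range(1, length):
            out[i] = np.searchsorted(cum_trans[out[i - 1]], u[i])
        return out


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSSM:
    """Log-odds scoring matrix derived from a position frequency matrix.

    ``log_freq[i, b]`` is the log of the pseudocount-smoothed motif frequency;
    ``weights[i, b] = log(freq / p_b)`` uses the background's stationary
    distribution, so with a 0-order background the window score is simply the
    sum of weights.  With the full Markov-1 background the scanner subtracts
    the conditional background log-likelihood instead.
    """

    motif_id: str
    counts: np.ndarray  # 4 x w, rows A,C,G,T
    pseudocount: float
    background: MarkovBackground
    log_freq: np.ndarray = field(init=False, repr=False)  # w x 4
    weights: np.ndarray = field(init=False, repr=False)  # w x 4

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise MotifError(f"{self.motif_id}: counts must be 4 x w with w >= 1")
        if np.any(counts < 0):
            raise MotifError(f"{self.motif_id}: negative counts")
        if np.any(counts.sum(axis=0) == 0):
            raise MotifError(f"{self.motif_id}: a position has all-zero counts")
        if self.pseudocount <= 0:
            raise MotifError(f"{self.motif_id}: pseudocount must be > 0")
        p = self.background.stationary()
        totals = counts.sum(axis=0)
        freq = (counts + self.pseudocount * p[:, None]) / (totals + self.pseudocount)
        log_freq = np.log(freq.T)  # w x 4
        object.__setattr__(self, "log_freq", log_freq)
        object.__setattr__(self, "weights", log_freq - np.log(p)[None, :])

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))


def pfm_to_pssm(
    counts: np.ndarray,
    pseudocount: float = 1.0,
    background: MarkovBackground | None = None,
    motif_id: str = "motif",
) -> PSSM:
    """Build a PSSM from raw position counts (4 x w, rows A,C,G,T)."""
    return PSSM(motif_id, np.asarray(counts, dtype=float), pseudocount,
                background or MarkovBackground.uniform())


def score_site(
    word: str | np.ndarray,
    pssm: PSSM,
    background: MarkovBackground,
    previous_base: str | int | None = None,
) -> float:
    """Log-odds of one w-mer: motif likelihood over Markov-1 background.

    The background likelihood of the first base is conditioned on
    ``previous_base`` when given, otherwise it uses the initial distribution.
    """
    arr = encode_sequence(word) if isinstance(word, str) else np.asarray(word)
    if arr.shape[0] != pssm.width:
        raise MotifError(f"word length {arr.shape[0]} != motif width {pssm.width}")
    if np.any(arr < 0):
        raise MotifError("word contains non-ACGT bases")
    motif_ll = float(pssm.log_freq[np.arange(pssm.width), arr].sum())
    if previous_base is None:
        bg = np.log(background.initial[arr[0]])
    else:
        prev = BASE_INDEX[previous_base] if isinstance(previous_base, str) else int(previous_base)
        bg = np.log(background.transition[prev, arr[0]])
    bg += float(np.log(background.transition[arr[:-1], arr[1:]]).sum())
    return motif_ll - bg


# ---------------------------------------------------------------------------
# exact score distribution (p-values)
# ---------------------------------------------------------------------------

@dataclass
class ScoreDistribution:
    """Discretized exact null distribution of the window score.

    ``pvalue(s)`` returns P(score >= s) for a window drawn from the Markov-1
    background (previous base at stationarity), monotone non-increasing in s.
    """

    bin_width: float
    scores: np.ndarray  # ascending bin centres
    pmf: np.ndarray
    survival: np.ndarray  # P(S >= scores[i])

    def pvalue(self, score) -> np.ndarray | float:
        s = np.asarray(score, dtype=float)
        # first bin centre >= s - bw/2 (bin containing s contributes)
        idx = np.searchsorted(self.scores, s - self.bin_width / 2, side="left")
        idx = np.minimum(idx, len(self.scores) - 1)
        out = self.survival[idx]
        out = np.where(s <= self.scores[0] + self.bin_width / 2, 1.0, out)
        too_high = s - self.bin_width / 2 > self.scores[-1]
        out = np.where(too_high, 0.0, out)
        return float(out) if np.isscalar(score) else out

    def score_at_pvalue(self, p: float) -> float:
        """Smallest bin centre whose survival is <= p."""
        idx = int(np.searchsorted(-self.survival, -p, side="left"))
        idx = min(idx, len(self.scores) - 1)
        return float(self.scores[idx])


def score_pvalue_table(
    pssm: PSSM, background: MarkovBackground, bin_width: float = 0.01
) -> ScoreDistribution:
    """Exact null score distribution by DP over (position, previous base).

    The previous base ahead of the window is drawn from the stationary
    distribution, matching an interior window of a long background sequence.
    """
    if bin_width <= 0:
        raise MotifError("bin_width must be > 0")
    w = pssm.width
    logf = pssm.log_freq  # w x 4
    logT = np.log(background.transition)
    pi = background.stationary()

    def to_bin(x: float) -> int:
        return int(round(x / bin_width))

    # dist[base] : dict bin -> probability, after emitting current position
    dist: list[dict[int, float]] = [dict() for _ in range(4)]
    for prev in range(4):
        for b in range(4):
            pr = pi[prev] * background.transition[prev, b]
            s = to_bin(logf[0, b] - logT[prev, b])
            dist[b][s] = dist[b].get(s, 0.0) + pr
    for i in range(1, w):
        new: list[dict[int, float]] = [dict() for _ in range(4)]
        for prev in range(4):
            for b in range(4):
                step = to_bin(logf[i, b] - logT[prev, b])
                tp = background.transition[prev, b]
                bucket = new[b]
                for s, pr in dist[prev].items():
                    key = s + step
                    bucket[key] = bucket.get(key, 0.0) + pr * tp
        dist = new
    total: dict[int, float] = {}
    for d in dist:
        for s, pr in d.items():
            total[s] = total.get(s, 0.0) + pr
    bins = np.array(sorted(total), dtype=float)
    pmf = np.array([total[int(b)] for b in bins])
    scores = bins * bin_width
    survival = pmf[::-1].cumsum()[::-1]
    return ScoreDistribution(bin_width, scores, pmf, survival)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteHit:
    """One predicted binding site (0-based, half-open coordinates)."""

    seq_id: str
    start: int
    end: int
    strand: str
    word: str
    score: float
    pvalue: float


def _window_scores(arr: np.ndarray, pssm: PSSM, background: MarkovBackground):
    """Forward-strand log-odds of every window; NaN where a window has N."""
    w = pssm.width
    n = arr.shape[0] - w + 1
    if n <= 0:
        return np.empty(0)
    safe = np.where(arr >= 0, arr, 0)
    valid = arr >= 0
    logT = np.log(background.transition)
    motif = np.zeros(n)
    ok = np.ones(n, dtype=bool)
    for i in range(w):
        motif += pssm.log_freq[i, safe[i : i + n]]
        ok &= valid[i : i + n]
    # background log-likelihood, conditioning each base on its predecessor
    bg = np.zeros(n)
    bg[0] = np.log(background.initial[safe[0]])
    if n > 1:
        trans = logT[safe[:-1], safe[1:]]  # P(arr[i+1] | arr[i])
        bg[1:] = trans[:n - 1]
        ok[1:] &= valid[:n - 1]  # previous base must be known
    inner = logT[safe[:-1], safe[1:]]
    # sum of transitions inside the window, positions 1..w-1 relative to start
    csum = np.concatenate([[0.0], np.cumsum(inner)])
    bg += csum[np.arange(n) + w - 1] - csum[np.arange(n)]
    scores = motif - bg
    scores[~ok] = np.nan
    return scores


def scan_sequences(
    sequences: list[tuple[str, str]],
    pssm: PSSM,
    background: MarkovBackground,
    p_threshold: float = 1e-5,
    score_threshold: float = 1.0,
    strands: str = "both",
    distribution: ScoreDistribution | None = None,
) -> list[SiteHit]:
    """Score every window on the requested strands and keep dual-threshold hits.

    Reverse-strand windows score the reverse complement against the forward
    background; the base preceding a minus-strand window is the complement of
    the base following it in sequence coordinates.  Windows containing
    non-ACGT bases are skipped and counted in a log message.
    """
    if not sequences:
        raise MotifError("empty sequence set")
    if strands not in ("both", "+", "-"):
        raise MotifError(f"bad strands {strands!r}")
    dist = distribution or score_pvalue_table(pssm, background)
    hits: list[SiteHit] = []
    skipped = 0
    w = pssm.width
    for seq_id, seq in sequences:
        arr = seq if isinstance(seq, np.ndarray) else encode_sequence(seq)
        n = arr.shape[0] - w + 1
        if n <= 0:
            continue
        strand_list = ["+", "-"] if strands == "both" else [strands]
        for strand in strand_list:
            if strand == "+":
                scores = _window_scores(arr, pssm, background)
                starts = np.arange(n)
            else:
                rc = reverse_complement(arr)
                rc_scores = _window_scores(rc, pssm, background)
                scores = rc_scores[::-1]  # index by forward-strand start
                starts = np.arange(n)
            bad = np.isnan(scores)
            skipped += int(bad.sum())
            cand = np.where(~bad & (scores >= score_threshold))[0]
            if cand.size == 0:
                continue
            pvals = dist.pvalue(scores[cand])
            keep = pvals <= p_threshold
            for pos, pv in zip(cand[keep], pvals[keep]):
                if strand == "+":
                    word = decode_sequence(arr[pos : pos + w])
                else:
                    word = decode_sequence(reverse_complement(arr[pos : pos + w]))
                hits.append(
                    SiteHit(seq_id, int(pos), int(pos + w), strand, word,
                            float(scores[pos]), float(pv))
                )
    if skipped:
        logger.info("scan_sequences: skipped %d windows containing non-ACGT bases", skipped)
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def hits_to_frame(hits: list[SiteHit]):
    """Hits as a BED-like DataFrame (seq, start, end, motif column order)."""
    import pandas as pd

    return pd.DataFrame(
        [(h.seq_id, h.start, h.end, h.word, round(h.score, 4), h.strand, h.pvalue)
         for h in hits],
        columns=["seq_id", "start", "end", "word", "score", "strand", "pvalue"],
    )


# ---------------------------------------------------------------------------
# interaction matrix + enrichment
# ---------------------------------------------------------------------------

def build_interaction_matrix(
    hits_by_tf: dict[str, list[SiteHit]],
    region_to_gene: dict[str, str],
    tfs: list[str],
    genes: list[str],
):
    """Binary TF x gene matrix: 1 iff the TF has a hit in a region of the gene.

    Returns (matrix DataFrame, row margins, column margins); genes with no
    mapped region get a warning and an all-zero column.
    """
    import pandas as pd

    if not region_to_gene:
        raise MotifError("region_to_gene map is empty")
    mapped_genes = set(region_to_gene.values())
    for g in genes:
        if g not in mapped_genes:
            warnings.warn(f"gene {g} has no mapped region; column will be all zero")
    mat = pd.DataFrame(0, index=list(tfs), columns=list(genes), dtype=int)
    for tf in tfs:
        for hit in hits_by_tf.get(tf, []):
            gene = region_to_gene.get(hit.seq_id)
            if gene in mat.columns:
                mat.loc[tf, gene] = 1
    return mat, mat.sum(axis=1), mat.sum(axis=0)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise MotifError(f"inconsistent margins K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise MotifError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


def randomization_test(
    count_targets,
    universe: list[str],
    observed_genes: list[str],
    group_size: int = 20,
    n_groups: int = 100,
    seed: int | None = None,
):
    """Enrichment of observed TF target counts against random gene groups.

    ``count_targets(genes)`` must return a mapping TF -> number of the given
    genes with at least one predicted site (the interaction-matrix row margin
    restricted to those genes).  ``n_groups`` groups of ``group_size`` genes
    are drawn from the universe; for each TF the observed count is compared to
    the pooled random counts with a one-sided hypergeometric (Fisher-style)
    tail test.
    """
    import pandas as pd

    if n_groups < 1:
        raise MotifError("n_groups must be >= 1")
    if len(universe) <= group_size:
        raise MotifError("universe must be larger than group_size")
    rng = np.random.default_rng(seed)
    observed = count_targets(list(observed_genes))
    pooled: dict[str, int] = {tf: 0 for tf in observed}
    for _ in range(n_groups):
        group = list(rng.choice(universe, size=group_size, replace=False))
        counts = count_targets(group)
        for tf, c in counts.items():
            pooled[tf] = pooled.get(tf, 0) + int(c)
    n_random = n_groups * group_size
    rows = []
    for tf, k_obs in sorted(observed.items()):
        K = pooled.get(tf, 0) + k_obs
        N = n_random + len(observed_genes)
        p = hypergeometric_tail(int(k_obs), int(K), len(observed_genes), int(N))
        rows.append((tf, int(k_obs), len(observed_genes), pooled.get(tf, 0), n_random, p))
    return pd.DataFrame(
        rows,
        columns=["tf", "observed_targets", "observed_genes",
                 "random_targets", "random_genes", "pvalue"],
    )
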