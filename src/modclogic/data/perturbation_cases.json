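[
 {
  "protein": "IRF4",
  "perturbation": "IRF4%0",
  "mode": "loss",
  "model_phenotype": "lack of most of moDC-specific markers",
  "checks": [
   {
    "csf2": 1,
    "il4": 1,
    "type": "markers_off_at_least",
    "lineage": "moDC",
    "count": 10
   },
   {
    "csf2": 1,
    "il4": 1,
    "type": "markers_on_at_least",
    "lineage": "moDC",
    "count": 1
   },
   {
    "csf2": 1,
    "il4": 1,
    "type": "classify_not",
    "label": "moDC"
   }
  ]
 },
 {
  "protein": "STAT6",
  "perturbation": "STAT6%1",
  "mode": "gain",
  "model_phenotype": "STAT6 is almost sufficient to achieve moDC differentiation",
  "checks": [
   {
    "csf2": 1,
    "il4": 0,
    "type": "component_equals",
    "component": "CD209",
    "level": 1
   },
   {
    "csf2": 1,
    "il4": 0,
    "type": "markers_on_at_least",
    "lineage": "moDC",
    "count": 15
   },
   {
    "csf2": 1,
    "il4": 0,
    "type": "classify_not",
    "label": "moDC"
   },
   {
    "csf2": 1,
    "il4": 0,
    "type": "classify_not",
    "label": "macrophage"
   }
  ]
 },
 {
  "protein": "PU1",
  "perturbation": "PU1%0",
  "mode": "loss",
  "model_phenotype": "abolish moDC and macrophage phenotype commitment",
  "checks": [
   {
    "csf2": 1,
    "il4": 1,
    "type": "classify_not",
    "label": "moDC"
   },
   {
    "csf2": 1,
    "il4": 0,
    "type": "classify_not",
    "label": "macrophage"
   }
  ]
 },
 {
  "protein": "IRF8",
  "perturbation": "IRF8%0",
  "mode": "loss",
  "model_phenotype": "abolish KLF4 expression and the entire macrophage differentiation",
  "checks": [
   {
    "csf2": 0,
    "il4": 1,
    "type": "component_equals",
    "component": "KLF4",
    "level": 0
   },
   {
    "csf2": 1,
    "il4": 0,
    "type": "markers_all_off",
    "lineage": "macrophage"
   },
   {
    "csf2": 1,
    "il4": 0,
    "type": "classify_not",
    "label": "macrophage"
   }
  ]
 },
 {
  "protein": "MAFB",
  "perturbation": "MAFB%0",
  "mode": "loss",
  "model_phenotype": "moDC differentiation is normal, macrophage differentiation is abolished",
  "checks": [
   {
    "csf2": 1,
    "il4": 1,
    "type": "state_equals_wild_type"
   },
   {
    "csf2": 1,
    "il4": 0,
    "type": "markers_all_off",
    "lineage": "macrophage"
   },
   {
    "csf2": 1,
    "il4": 0,
    "type": "classify_not",
    "label": "macrophage"
   }
  ]
 },
 {
  "protein": "NCOR2",
  "perturbation": "NCOR2%0",
  "mode": "loss",
  "model_phenotype": "lack of moDC-specific markers",
  "checks": [
   {
    "csf2": 1,
    "il4": 1,
    "type": "markers_all_off",
    "lineage": "moDC"
   }
  ]
 },
 {
  "protein": "AHR",
  "perturbation": "AHR%0",
  "mode": "loss",
  "model_phenotype": "lack of every moDC-specific marker, macrophage differentiation is normal",
  "checks": [
   {
    "csf2": 1,
    "il4": 1,
    "type": "markers_all_off",
    "lineage": "moDC"
   },
   {
    "csf2": 1,
    "il4": 0,
    "type": "state_equals_wild_type"
   }
  ]
 },
 {
  "protein": "JAK3",
  "perturbation": "JAK3%0",
  "mode": "loss",
  "model_phenotype": "macrophage phenotype with CSF2 and IL4; macrophage differentiation unaffected",
  "checks": [
   {
    "csf2": 1,
    "il4": 1,
    "type": "classify_equals",
    "label": "macrophage"
   },
   {
    "csf2": 1,
    "il4": 0,
    "type": "state_equals_wild_type"
   }
  ]
 },
 {
  "protein": "CEBPB",
  "perturbation": "CEBPB%0",
  "mode": "loss",
  "model_phenotype": "lack of some specific macrophage markers",
  "checks": [
   {
    "csf2": 1,
    "il4": 0,
    "type": "classify_equals",
    "label": "macrophage"
   },
   {
    "csf2": 1,
    "il4": 0,
    "type": "markers_off_at_least",
    "lineage": "macrophage",
    "count": 1
   },
   {
    "csf2": 1,
    "il4": 0,
    "type": "component_equals",
    "component": "CCDC151",
    "level": 1
   },
   {
    "csf2": 1,
    "il4": 0,
    "type": "component_equals",
    "component": "CD206",
    "level": 1
   }
  ]
 }
]
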