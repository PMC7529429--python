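{
 "auxotrophy": {
  "essential_nutrients": [
   "EX_mon2_e",
   "EX_mon4_e"
  ],
  "scanned": 6
 },
 "conditions": {
  "AP": {
   "objective_id": "ATPM",
   "reactions": 25,
   "reduced_optimum": 260.0,
   "removed_blocked": 27,
   "removed_unsupported": 11,
   "sampling": {
    "n": 200,
    "seed": 7,
    "thinning": 5
   },
   "source_optimum": 260.0
  },
  "GP": {
   "objective_id": "BIOMASS",
   "reactions": 52,
   "reduced_optimum": 6.6315736694677865,
   "removed_blocked": 5,
   "removed_unsupported": 6,
   "sampling": {
    "n": 200,
    "seed": 7,
    "thinning": 5
   },
   "source_optimum": 6.6315736694677865
  }
 },
 "diff": {
  "AP_only": 9,
  "GP_only": 36,
  "shared": 16
 },
 "essentiality": {
  "essential": 12,
  "screened": 47,
  "threshold": 0.1,
  "wild_type_growth": 6.6315736694677865
 },
 "model": {
  "compartments": [
   "c",
   "e",
   "p"
  ],
  "exchanges": 15,
  "genes": 22,
  "metabolites": 54,
  "model_id": "toy_gem_seed7",
  "objective_id": "BIOMASS",
  "reactions": 63
 },
 "parameters": {
  "essentiality_threshold": 0.1,
  "expression_threshold": 10.0,
  "growth_tolerance": 1e-06,
  "objective_fraction": 0.9
 },
 "quality": {
  "balance_counts": {
   "balanced": 46,
   "skipped": 16,
   "unverifiable": 1
  },
  "dead_end_metabolites": 2,
  "dead_end_reactions": 2
 },
 "stages": [
  "load",
  "quality",
  "auxotrophy",
  "essentiality",
  "reduce+sample[AP]",
  "reduce+sample[GP]",
  "diff"
 ]
}
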