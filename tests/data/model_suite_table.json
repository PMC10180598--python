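{
  "_comment": "Term-by-term transcription of the published MET model scheme: 13 models (RCBD baseline + 6 incomplete sub-blocking + 6 complete-blocking variants). Autoregressive residuals apply to all 12 post hoc models; *HETERO/PCA1 rows carry a trial-specific nugget, the others a shared one.",
  "RCBD": {
    "name": "RCBD",
    "fixed_terms": ["intercept"],
    "random_terms": ["additive", "family_x_trial", "rep(trial)", "trial(series)", "series", "provenance"],
    "residual": "iid_simple",
    "blocking": null
  },
  "SUBB": {
    "name": "SUBB",
    "fixed_terms": ["intercept", "x(trial)", "y(trial)", "trial"],
    "random_terms": ["additive", "family_x_trial", "rep(trial)", "subrow(trial)", "subcol(trial)"],
    "residual": "ar1_plus_iid",
    "blocking": "incomplete"
  },
  "SUBHETERO": {
    "name": "SUBHETERO",
    "fixed_terms": ["intercept", "x(trial)", "y(trial)", "trial"],
    "random_terms": ["additive", "family_x_trial", "rep(trial)", "subrow(trial)", "subcol(trial)"],
    "residual": "ar1_plus_hetero",
    "blocking": "incomplete"
  },
  "SUBNN": {
    "name": "SUBNN",
    "fixed_terms": ["intercept", "x(trial)", "y(trial)", "trial", "competition(trial)"],
    "random_terms": ["additive", "family_x_trial", "rep(trial)", "subrow(trial)", "subcol(trial)"],
    "residual": "ar1_plus_iid",
    "blocking": "incomplete"
  },
  "SUBNNHETERO": {
    "name": "SUBNNHETERO",
    "fixed_terms": ["intercept", "x(trial)", "y(trial)", "trial", "competition(trial)"],
    "random_terms": ["additive", "family_x_trial", "rep(trial)", "subrow(trial)", "subcol(trial)"],
    "residual": "ar1_plus_hetero",
    "blocking": "incomplete"
  },
  "SUBNNPCA1": {
    "name": "SUBNNPCA1",
    "fixed_terms": ["intercept", "x(trial)", "y(trial)", "trial", "pc1-3(trial)"],
    "random_terms": ["additive", "family_x_trial", "rep(trial)", "subrow(trial)", "subcol(trial)"],
    "residual": "ar1_plus_hetero",
    "blocking": "incomplete"
  },
  "SUBNNPCA2": {
    "name": "SUBNNPCA2",
    "fixed_terms": ["intercept", "x(trial)", "y(trial)", "trial", "competition(trial)", "pc1-3(trial)"],
    "random_terms": ["additive", "family_x_trial", "rep(trial)", "subrow(trial)", "subcol(trial)"],
    "residual": "ar1_plus_iid",
    "blocking": "incomplete"
  },
  "BLOCKING": {
    "name": "BLOCKING",
    "fixed_terms": ["intercept", "x(trial)", "y(trial)", "trial"],
    "random_terms": ["additive", "family_x_trial", "rep(trial)", "rowblock(trial)", "colblock(trial)"],
    "residual": "ar1_plus_iid",
    "blocking": "complete"
  },
  "BLKHETERO": {
    "name": "BLKHETERO",
    "fixed_terms": ["intercept", "x(trial)", "y(trial)", "trial"],
    "random_terms": ["additive", "family_x_trial", "rep(trial)", "rowblock(trial)", "colblock(trial)"],
    "residual": "ar1_plus_hetero",
    "blocking": "complete"
  },
  "BLKNN": {
    "name": "BLKNN",
    "fixed_terms": ["intercept", "x(trial)", "y(trial)", "trial", "competition(trial)"],
    "random_terms": ["additive", "family_x_trial", "rep(trial)", "rowblock(trial)", "colblock(trial)"],
    "residual": "ar1_plus_iid",
    "blocking": "complete"
  },
  "BLKNNHETERO": {
    "name": "BLKNNHETERO",
    "fixed_terms": ["intercept", "x(trial)", "y(trial)", "trial", "competition(trial)"],
    "random_terms": ["additive", "family_x_trial", "rep(trial)", "rowblock(trial)", "colblock(trial)"],
    "residual": "ar1_plus_hetero",
    "blocking": "complete"
  },
  "NNPCA1": {
    "name": "NNPCA1",
    "fixed_terms": ["intercept", "x(trial)", "y(trial)", "trial", "pc1-3(trial)"],
    "random_terms": ["additive", "family_x_trial", "rep(trial)", "rowblock(trial)", "colblock(trial)"],
    "residual": "ar1_plus_hetero",
    "blocking": "complete"
  },
  "NNPCA2": {
    "name": "NNPCA2",
    "fixed_terms": ["intercept", "x(trial)", "y(trial)", "trial", "competition(trial)", "pc1-3(trial)"],
    "random_terms": ["additive", "family_x_trial", "rep(trial)", "rowblock(trial)", "colblock(trial)"],
    "residual": "ar1_plus_iid",
    "blocking": "complete"
  }
}
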