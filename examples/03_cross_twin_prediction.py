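"""Cross-twin prediction of G-scores: MZ-like vs DZ-like conditions.

For each condition, one member of every pair trains a screened PLSR model
and the co-twins test it, over bootstrapped twin splits with a
full-pipeline permutation null.  Desk-scale settings (B = 25 splits, 10
permutations per model) keep the run under a couple of minutes.
"""

import warnings

from twinconn import (
    RHO_DZ,
    RHO_MZ,
    TwinSimParams,
    adjust_cohort,
    generate_cohort,
    run_logocv_bootstrap,
)

for label, rho in (("MZ-like", RHO_MZ), ("DZ-like", RHO_DZ)):
    syn = generate_cohort(
        TwinSimParams(n_pairs=80, node_count=40, rho=rho, seed=3)
    )
    cohort = adjust_cohort(syn.cohort)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_logocv_bootstrap(
            cohort, "MZ", B=25, perms_per_model=10,
            component_grid_max=20, inner_folds=5, seed=4,
        )
    print(f"{label} (rho = {rho}): mean test r = {res.mean_r:.3f}, "
          f"p_perm = {res.p_perm:.4f} "
          f"({res.per_iteration_r.size} models, "
          f"{res.null_draws.size} null draws)")

print("A significant mean r in the high-similarity condition only mirrors "
      "the study's contrast: intelligence-related connectivity transfers "
      "across genetically identical co-twins.")
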