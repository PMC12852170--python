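"""Score a bulk transplant cohort and stratify graft survival.

Simulates a 300-biopsy microarray-like cohort (plus 4 nephrectomy
controls and 12 longitudinal patients) whose latent injury score is
elevated in rejection and linked to graft loss, scores every biopsy
against a 20-gene injury marker set (control-normalized log2 geometric
mean), splits at the full-cohort median, and compares above- vs
below-median survival within TCMR over a 3-year horizon.
"""

from graftstates import (
    longitudinal_trajectories,
    score_samples,
    survival_by_score,
)
from graftstates.simulate import default_config, simulate_bulk_cohort

config = default_config(seed=1)
config.bulk.n_longitudinal = 12
marker_sets = [("PT Injury 2", [f"gene{i:04d}" for i in range(20)])]

cohort, truth = simulate_bulk_cohort(config, marker_sets)
scores = score_samples(cohort, marker_sets)

controls = scores.values.loc[cohort.controls, "PT Injury 2"]
print(f"control scores (mean must be 0): {controls.round(3).to_list()}")
print("mean score by diagnosis (log2 vs nephrectomy):")
first = cohort.first_biopsies()
print(scores.values.loc[first.index, "PT Injury 2"]
      .groupby(first["diagnosis"]).mean().round(2))

surv = survival_by_score(cohort, scores, diagnoses=("TCMR", "NR"), horizon=36.0)
print("\nmedian-split log-rank within TCMR (fdr across sets):")
print(surv.tests[["n_above", "n_below", "events", "chi2", "p", "fdr"]].round(4))
print("compact letters (strata sharing a letter are not separable):")
print(surv.letters["PT Injury 2"])

traj = longitudinal_trajectories(scores, cohort)
print("\nscore persistence in TCMR -> NR resolvers (mean by biopsy):")
print(traj.groupby("biopsy_index")["score"].mean().round(2))
# scores stay elevated after the molecular diagnosis returns to NR --
# the injury signature outlives the rejection episode
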