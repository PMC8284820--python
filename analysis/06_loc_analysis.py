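#!/usr/bin/env python
"""The locus-of-control analysis layer on the synthetic cohort.

Covers, on the 35-subject paper-like cohort: questionnaire psychometrics
(varimax factor analysis, Cronbach's alpha), exclusion screening,
model-agnostic outcome measures, permutation correlation tests of
I/C/P scores against g+ choice frequency with FDR control, the
power justification for n = 35, and random-forest importance of the
fitted parameters for I-score prediction.

Writes tables under results/loc/.
"""

from pathlib import Path

import pandas as pd

from ctrltask.cohort import load_cohort
from ctrltask.loc import (cohort_outcomes, cronbach_alpha, exclusion_screen,
                          fdr_correct, permutation_corr_test,
                          power_correlation, rf_importance,
                          varimax_factor_analysis)

SEED = 2031
OUT = Path("results")
LOC = OUT / "loc"


def main():
    LOC.mkdir(parents=True, exist_ok=True)
    data = load_cohort(OUT / "cohort")
    items = data["items"].drop(columns="subject_id").to_numpy(float)
    subjects = data["subjects"]

    # --- psychometrics
    fa = varimax_factor_analysis(items, n_factors=4)
    print(f"factor analysis: cumulative variance of 4 rotated factors "
          f"{fa['cumulative_variance']:.2f}, chi^2 p = {fa['chi2_p']:.3f}")
    alphas = {}
    for i, scale in enumerate(("I", "C", "P")):
        a, (lo, hi) = cronbach_alpha(items[:, i * 8:(i + 1) * 8],
                                     n_boot=1000, seed=SEED)
        alphas[scale] = (a, lo, hi)
        print(f"Cronbach alpha {scale}: {a:.2f} [95% CI {lo:.2f}, {hi:.2f}]")
    pd.DataFrame([{"scale": s, "alpha": a, "ci_low": lo, "ci_high": hi}
                  for s, (a, lo, hi) in alphas.items()]
                 ).to_csv(LOC / "cronbach.csv", index=False)

    # --- outcomes, exclusions, correlations
    outcomes = cohort_outcomes(data["trials"])
    outcomes.to_csv(LOC / "outcomes.csv", index=False)
    merged = outcomes.merge(subjects, on="subject_id")
    high = merged[merged.condition == "high"]
    flagged = exclusion_screen(high.catch_accuracy.to_numpy(),
                               high.I.to_numpy())
    print(f"exclusion screen: {len(flagged)} subject(s) flagged {flagged}")

    print(f"power to detect rho = 0.45 at n = 35: "
          f"{power_correlation(35, 0.45, 0.05):.2f}")

    rows = []
    for cond in ("high", "low"):
        sub = merged[merged.condition == cond]
        for score in ("I", "C", "P"):
            r, p, _ = permutation_corr_test(sub[score], sub.gplus_frequency,
                                            n_perm=10_000, seed=SEED)
            rows.append({"condition": cond, "score": score, "r": r,
                         "p_perm": p})
    corr = pd.DataFrame(rows)
    corr["significant_fdr"] = fdr_correct(corr.p_perm, q=0.05)
    corr.to_csv(LOC / "score_correlations.csv", index=False)
    print("\nscore vs g+ choice frequency (permutation tests, BH-FDR):")
    print(corr.round(3).to_string(index=False))

    # --- parameter importance for I-scores
    fits_path = OUT / "fits_vehicle_rw.csv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path)
        for cond in ("high", "low"):
            sub = fits[fits.condition == cond].merge(
                subjects[["subject_id", "I"]], on="subject_id")
            params = sub.drop(columns=["subject_id", "condition", "nll", "I"])
            params = params.dropna(axis=1)
            imp = rf_importance(params, sub.I.to_numpy(), n_repeats=50,
                                seed=SEED)
            imp.to_csv(LOC / f"rf_importance_{cond}.csv")
            print(f"\nRF importance for I-scores ({cond} influence):")
            print(imp.sort_values("importance",
                                  ascending=False).round(3).to_string())


if __name__ == "__main__":
    main()
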