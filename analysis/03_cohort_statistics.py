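"""Cohort statistics on a 400-patient summary-level cohort.

Draws patient summaries from the covariate model (age shifts the
morphology-class mix; mean ICP shifts pulse amplitude; both feed a
logistic mortality model), then runs the full statistical battery:
quartile categorization, 4x4 factorial ANOVA with partial eta-squared
and Bonferroni post-hoc tests, dummy-variable multiple regression, group
t-tests by survival, and logistic regression with ROC/AUC including
backward elimination in the multivariate model.
"""

import json
from pathlib import Path

import icpmorph as im

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = im.CohortSimConfig(n_patients=400, seed=7_777)
    df = im.synth_cohort_summaries(cfg)
    report: list[str] = []

    fa = im.quartile_boundaries(df["age"], "age")
    fb = im.quartile_boundaries(df["mean_icp"], "mean_icp")
    report.append(f"quartile boundaries: age {fa.boundaries} years, "
                  f"mean ICP {fb.boundaries} mm Hg")

    out = {}
    for resp in ("psi", "amp_icp"):
        res = im.factorial_anova(df, resp, fa, fb)
        out[f"anova_{resp}"] = res.terms.to_dict(orient="index")
        report.append(f"--- {resp} ---")
        report.append(res.report())

    for resp in ("psi", "amp_icp"):
        reg = im.multiple_regression(df, resp)
        out[f"regression_{resp}"] = {"beta": reg.beta.to_dict(),
                                     "p": reg.p_values.to_dict(),
                                     "r2": reg.r_squared, "n": reg.n}
        report.append(f"{resp} regression: beta_age = "
                      f"{reg.beta['age']:.3f}, beta_icp = "
                      f"{reg.beta['mean_icp']:.3f}, max VIF = "
                      f"{reg.vif.max():.2f}")

    for resp in ("mean_icp", "amp_icp", "psi", "age"):
        t = im.group_ttest(df, resp)
        report.append(t.report(f"{resp} died-vs-survived"))

    logi = {}
    for pred in ("amp_icp", "psi", "age", "mean_icp"):
        r = im.logistic_auc(df, [pred])
        logi[pred] = {"chi2": r.chi2, "df": r.df, "p": r.p, "auc": r.auc,
                      "auc_se": r.auc_se}
        report.append(f"{pred} vs mortality: chi2({r.df}) = {r.chi2:.2f}, "
                      f"p = {r.p:.3g}, AUC = {r.auc:.2f}")
    multi = im.logistic_auc(df, ["amp_icp", "psi", "age", "mean_icp"],
                            eliminate=True)
    logi["multivariate"] = {"chi2": multi.chi2, "df": multi.df,
                            "p": multi.p, "auc": multi.auc,
                            "retained": multi.retained}
    report.append(f"multivariate: retained {multi.retained}, "
                  f"chi2({multi.df}) = {multi.chi2:.2f}, "
                  f"AUC = {multi.auc:.2f}")
    out["logistic"] = logi

    (RESULTS / "cohort_statistics.json").write_text(
        json.dumps(out, indent=2))
    (RESULTS / "cohort_statistics.txt").write_text("\n".join(report) + "\n")
    print("\n".join(report))


if __name__ == "__main__":
    main()
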