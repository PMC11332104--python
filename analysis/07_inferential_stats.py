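"""Inferential layer over the stratified benchmark.

Treats the benchmarked model grids as paired units:

* paired t-test (with Cohen's d = t/sqrt(n) and the default-prior JZS
  Bayes factor) of model NSS for women vs men;
* Greenhouse-Geisser-corrected repeated-measures ANOVA on the percentage
  of explainable NSS across age bins, plus Bonferroni-corrected pairwise
  contrasts between bins.

With only the handful of synthetic model grids the tests are illustrative
of the machinery, not powered; the same code applies unchanged to a full
model battery. Writes stats_gender.csv, stats_age_anova.csv and
stats_age_contrasts.csv.
"""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gazebench.stats import bonferroni_contrasts, paired_t, rm_anova_gg

ROOT = Path(__file__).resolve().parents[1] / "results"
BASELINES = {"fixation_map", "central_bias", "single_observer"}


def main() -> None:
    gender = pd.read_csv(ROOT / "benchmark_gender.csv")
    models = gender[~gender["map_id"].isin(BASELINES)]
    wide = models.pivot(index="map_id", columns="stratum", values="nss")
    res = paired_t(wide["woman"].to_numpy(), wide["man"].to_numpy())
    pd.DataFrame([dataclasses.asdict(res)]).to_csv(ROOT / "stats_gender.csv", index=False)
    print(
        f"women vs men (n = {res.n} models): t({res.df}) = {res.t:.3f}, "
        f"p = {res.p:.3f}, d = {res.cohens_d:.3f}, BF10 = {res.bf10:.3f}"
    )

    expl = pd.read_csv(ROOT / "age_bin_explained_pct.csv")
    wide = expl.pivot(index="map_id", columns="stratum", values="explained_pct")
    anova = rm_anova_gg(wide.to_numpy())
    pd.DataFrame([dataclasses.asdict(anova)]).to_csv(ROOT / "stats_age_anova.csv", index=False)
    print(
        f"age bins: F({anova.df1:.3f},{anova.df2:.3f}) = {anova.F:.3f}, "
        f"p = {anova.p:.4g}, eps_GG = {anova.epsilon_gg:.3f}, eta^2 = {anova.eta_sq:.3f}"
    )
    contrasts = bonferroni_contrasts(wide)
    contrasts.to_csv(ROOT / "stats_age_contrasts.csv", index=False)
    sig = contrasts[contrasts["p_bonferroni"] < 0.05]
    print(f"{len(contrasts)} pairwise bin contrasts, {len(sig)} significant after Bonferroni")


if __name__ == "__main__":
    main()
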