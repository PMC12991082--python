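#!/usr/bin/env python
"""Trajectory statistics: interaction, Johnson-Neyman, piecewise, LOESS overlay.

Runs the full statistical layer on simulated cohorts:

* the end-to-end experiment (phantom cohort -> measured tortuosity ->
  age x group interaction over the early-life window);
* Johnson-Neyman significance intervals for a conditional CAA effect whose
  quadratic is constructed from the young/old boundaries (7.3 / 15 months);
* piecewise regression at the 8-month knot;
* z-scored LOESS overlay of a mouse-like and human-like late-rise curve.

Writes results/interaction_fit.csv, results/jn_intervals.csv,
results/loess_overlay.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from vasotrace import synthgen as sg
from vasotrace import trajstats as ts
from vasotrace import workflow as wf


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-runs", type=int, default=20)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rate, cohort = wf.interaction_detection_rate(args.n_runs, seed=args.seed)
    early = cohort[cohort.age <= 12.0]
    fit = ts.fit_interaction_model(early, "tortuosity", "group", "age")
    pd.DataFrame({"term": ["intercept", "group", "age", "age_x_group"],
                  "coef": fit.params, "se": fit.bse,
                  "p": fit.pvalues}).to_csv(
        args.out / "interaction_fit.csv", index=False)
    print(f"interaction detected in {rate:.0%} of {args.n_runs} cohorts; "
          f"example age x group p = {fit.pvalues[3]:.2g}")

    # Johnson-Neyman intervals around the young/old boundaries
    r1, r2, df, curvature = 7.3, 15.0, 219, 0.95
    t_crit = sps.t.ppf(0.975, df)
    b3 = 1.0
    cov = np.zeros((4, 4))
    cov[3, 3] = (b3 ** 2 - curvature) / t_crit ** 2
    b1 = -curvature * (r1 + r2) / 2
    cov[1, 1] = (b1 ** 2 - curvature * r1 * r2) / t_crit ** 2
    jn_fit = ts.InteractionModelFit(params=np.array([0.0, b1, 0.0, b3]),
                                    cov=cov, df_resid=df, n=df + 4)
    jn = ts.johnson_neyman(jn_fit, (3.0, 18.0))
    pd.DataFrame({"boundary_months": jn.boundaries}).to_csv(
        args.out / "jn_intervals.csv", index=False)
    print(f"JN boundaries: {jn.boundaries[0]:.2f} and {jn.boundaries[1]:.2f} "
          f"months; significant regions {jn.significant_regions}")

    # piecewise regression of tortuosity on amyloid by age side of 8 months
    rng = np.random.default_rng(args.seed)
    age = rng.uniform(3, 18, 200)
    caa = sg.sigmoid(age, 0, 25, 0.8, 12.0) + rng.normal(0, 2, 200)
    tau = 1.1 + np.where(age <= 8, 0.01 * caa, 0.0) + rng.normal(0, 0.02, 200)
    tab = pd.DataFrame({"age": age, "caa": caa, "tau": tau})
    lo, hi = ts.piecewise_fit(tab, "tau", "caa", split_var="age", knot=8.0)
    print(f"piecewise: CAA slope below 8 mo = {lo.slope:.4f} (p = {lo.pvalue:.2g}); "
          f"above 8 mo = {hi.slope:.4f} (p = {hi.pvalue:.2g})")

    # cross-species overlay: late-rise tortuosity in mouse months / human years
    mouse_age = np.linspace(3, 18, 60)
    human_age = np.linspace(45, 85, 60)
    mouse = sg.sigmoid(mouse_age, 1.10, 1.40, 0.9, 14.0) \
        + rng.normal(0, 0.01, 60)
    human = sg.sigmoid(human_age, 1.20, 1.60, 0.35, 75.0) \
        + rng.normal(0, 0.01, 60)
    overlay = ts.zscore_align((mouse_age, mouse), (human_age, human),
                              labels=("mouse", "human"))
    overlay.to_csv(args.out / "loess_overlay.csv", index=False)
    gap = np.abs(overlay["z_mouse"] - overlay["z_human"]).max()
    print(f"z-scored overlay: max cross-species gap = {gap:.2f} z on the "
          f"shared normalized-age grid")


if __name__ == "__main__":
    main()
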