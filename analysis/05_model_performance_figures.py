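#!/usr/bin/env python
"""Model-performance figures from the stored study-replica run.

Reads results/run/ (produced by 04_run_study_replica.py) and renders:

    results/fig_model_comparison.png   explained variance and RMSE of the
                                       four models for both criteria
    results/fig_bias_distributions.png best-model estimation-error
                                       distributions: overall, by sex, by
                                       age tertile and BMI category

Also prints the per-model evaluation table with RMSE in METs.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from wristpaee.evaluation import to_mets

results = Path(__file__).resolve().parent.parent / "results"
run = results / "run"
if not run.exists():
    raise SystemExit("run 04_run_study_replica.py first")

eval_models = pd.read_csv(run / "evaluation_models.csv")
paee = eval_models[eval_models["outcome"] == "paee"].copy()
paee["rmse_mets"] = to_mets(paee["rmse"])
trunk = eval_models[eval_models["outcome"] == "trunk_acc"]
print(paee.round(3).to_string(index=False))

fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
labels = [f"M{m}\n{r.metric.upper()} {r.form[:4]}"
          for m, r in paee.set_index("model").iterrows()]
axes[0].bar(labels, 100 * paee["r2_between"], color="#4477aa")
axes[0].set_ylabel("between-individual $R^2$ (%)")
axes[0].set_title("PAEE explained variance")
axes[1].bar(labels, paee["rmse"], color="#ee6677")
axes[1].set_ylabel("RMSE (J·min$^{-1}$·kg$^{-1}$)")
axes[1].set_ylim(paee["rmse"].min() * 0.95, paee["rmse"].max() * 1.02)
axes[1].set_title("PAEE RMSE")
axes[2].bar(labels, 100 * trunk["r2_between"].to_numpy(), color="#228833")
axes[2].set_ylabel("between-individual $R^2$ (%)")
axes[2].set_title("trunk acceleration explained variance")
fig.tight_layout()
fig.savefig(results / "fig_model_comparison.png", dpi=150)

strat = pd.read_csv(run / "stratified_bias.csv")
best = pd.read_csv(run / "evaluation_best.csv")
fig, axes = plt.subplots(1, 3, figsize=(11, 3.2), sharey=True)
for ax, stratum in zip(axes, ("sex", "age_tertile", "bmi_category")):
    sub = strat[strat["stratum"] == stratum]
    ax.bar(sub["level"], sub["mean_bias"], yerr=sub["sd"], capsize=4,
           color="#ccbb44")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_title(f"bias by {stratum.replace('_', ' ')}")
    ax.tick_params(axis="x", rotation=20)
axes[0].set_ylabel("mean bias (J·min$^{-1}$·kg$^{-1}$)")
fig.suptitle("best model (M%d): mean bias %.2f, LoA [%.1f, %.1f]" % (
    best["model"].iloc[0], best["mean_bias"].iloc[0],
    best["loa_lower"].iloc[0], best["loa_upper"].iloc[0]), y=1.02)
fig.tight_layout()
fig.savefig(results / "fig_bias_distributions.png", dpi=150,
            bbox_inches="tight")
print("\nfigures written to", results)
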