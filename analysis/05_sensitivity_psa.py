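"""Probabilistic sensitivity analysis and acceptability curve.

Runs 1000 Monte-Carlo iterations sampling utilities (gamma), unit costs
(log-normal) and parametric tail parameters (multivariate normal via the
Cholesky factor of each fit covariance), then reports the incremental
cloud, the median ICER and the cost-effectiveness acceptability curve.
"""

import json

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from psmcea.config import reference_config
from psmcea.model import CEModel
from psmcea.sensitivity import ceac, run_psa
from psmcea.synthetic import read_trial

OUT = "results"


def main():
    config = reference_config()
    model = CEModel(config, read_trial(OUT)).fit()
    result = run_psa(model)
    result.samples.to_csv(f"{OUT}/psa_samples.csv", index=False)
    summary = result.summary()
    with open(f"{OUT}/psa_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(json.dumps(summary, indent=2))

    grid = np.arange(0.0, config.psa.wtp_grid_max + 1, config.psa.wtp_grid_step)
    curve = ceac(result.samples, grid)
    curve.to_csv(f"{OUT}/ceac.csv", index=False)
    crossing = curve[curve["probability"] >= 0.5]
    if len(crossing):
        print(f"50% cost-effective at ~EUR {crossing['wtp'].iloc[0]:,.0f}/QALY")

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4.5))
    ax1.scatter(result.samples["delta_qaly"], result.samples["delta_cost"], s=6, alpha=0.4)
    ax1.axhline(0, color="k", lw=0.8)
    ax1.axvline(0, color="k", lw=0.8)
    ax1.set_xlabel("incremental QALYs")
    ax1.set_ylabel("incremental cost (EUR)")
    ax2.plot(curve["wtp"], curve["probability"])
    ax2.set_xlabel("willingness to pay (EUR/QALY)")
    ax2.set_ylabel("P(cost-effective)")
    ax2.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(f"{OUT}/figures_psa.png", dpi=120)


if __name__ == "__main__":
    main()
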