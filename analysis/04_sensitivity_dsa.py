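"""One-way (tornado) deterministic sensitivity analysis.

Each input is moved to its published low/high bound with everything else at
base and the model fully re-evaluated; bars are sorted by their effect on
the ICER.  Age enters as a zero-width bar by construction (no background
mortality links it to outcomes).
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from psmcea.config import reference_config
from psmcea.model import CEModel
from psmcea.sensitivity import run_dsa
from psmcea.synthetic import read_trial

OUT = "results"


def main():
    config = reference_config()
    model = CEModel(config, read_trial(OUT)).fit()
    tornado = run_dsa(model)
    tornado.to_csv(f"{OUT}/dsa_tornado.csv", index=False)
    print(tornado[["parameter", "icer_at_low", "icer_at_high", "width"]].round(0).to_string(index=False))

    top = tornado[tornado["width"] > 0]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(top) + 1))
    base = tornado["icer_base"].iloc[0]
    ax.barh(top["parameter"], top["icer_at_high"] - base, left=base, color="#c44", label="high")
    ax.barh(top["parameter"], top["icer_at_low"] - base, left=base, color="#48a", label="low")
    ax.axvline(base, color="k", lw=1)
    ax.set_xlabel("ICER (EUR/QALY)")
    ax.invert_yaxis()
    ax.legend()
    fig.tight_layout()
    fig.savefig(f"{OUT}/figures_tornado.png", dpi=120)
    print(f"\nbase ICER EUR {base:,.0f}/QALY; widest bar: {tornado['parameter'].iloc[0]}")


if __name__ == "__main__":
    main()
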