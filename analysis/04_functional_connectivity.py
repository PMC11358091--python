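"""Band-averaged coherence and mutual information, within and between regions.

Builds channel x channel adjacency matrices per epoch, summarizes them
into within-region (F, P, O) and between-region (F-P, F-O, P-O) means,
and prints the condition contrast (both metrics drop in the SCZ-like
cohort).
"""

import importlib.util
from pathlib import Path

import pandas as pd

from ecognet import SpectralParams
from ecognet.layout import default_layout
from ecognet.pipeline import _epoch_connectivity_rows

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

_spec = importlib.util.spec_from_file_location(
    "complexity_step", Path(__file__).parent / "03_complexity.py"
)
_step3 = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_step3)


def main():
    epochs = _step3.load_processed()
    layout = default_layout()
    rows = []
    for rec in epochs:
        if not rec.excluded:
            rows.extend(_epoch_connectivity_rows(rec, layout, SpectralParams(), 16))
    conn = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    conn.to_csv(RESULTS / "connectivity_summaries.csv", index=False)
    print(f"{len(conn)} region-summary rows written")
    print("\ncondition means by scope:")
    print(
        conn.groupby(["condition", "scope"])[["coherence", "mi"]]
        .mean().round(4).to_string()
    )


if __name__ == "__main__":
    main()
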