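"""Permutation entropy and permutation LZ complexity of every channel-epoch.

Reads the preprocessed demo cohort, computes the per-channel complexity
table (m = 4, tau = 1) and prints the whole-brain contrast between
conditions; the SCZ-like cohort is constructed to be more irregular.
"""

from pathlib import Path

from ecognet import EmbeddingParams
from ecognet.complexity import complexity_table, whole_brain_means
from ecognet.layout import default_layout
from ecognet.recording import load_manifest_epochs, read_manifest

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "scratch" / "demo_cohort"
RESULTS = ROOT / "results"


def load_processed():
    manifest = read_manifest(COHORT / "manifest.csv")
    manifest = manifest.assign(path=manifest["path"].str.replace(".csv", "_proc.csv", regex=False))
    return load_manifest_epochs(manifest, base=COHORT)


def main():
    epochs = load_processed()
    table = complexity_table(epochs, default_layout(), EmbeddingParams(m=4, tau=1))
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "complexity_table.csv", index=False)
    print(f"{len(table)} channel-epoch rows written")
    wb = table.groupby("condition")[["pe", "plzc"]].mean()
    print("\nwhole-brain means:")
    print(wb.round(4).to_string())
    print("\nsubject-level means:")
    print(whole_brain_means(table).round(4).to_string(index=False))


if __name__ == "__main__":
    main()
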