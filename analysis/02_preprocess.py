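"""Preprocess the demo cohort: 256 Hz, notch 50/100 Hz, 55-95 Hz band, artifact mask.

Reads the manifest written by 01, applies the preprocessing chain to
every epoch, writes the processed epochs next to the originals (suffix
``_proc``) and an exclusion report to results/.
"""

from pathlib import Path

from ecognet import PreprocessParams
from ecognet.preprocess import exclusion_report, preprocess_recording
from ecognet.recording import load_manifest_epochs, read_manifest, write_epoch_csv

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "scratch" / "demo_cohort"
RESULTS = ROOT / "results"


def main():
    manifest = read_manifest(COHORT / "manifest.csv")
    epochs = load_manifest_epochs(manifest, base=COHORT)
    params = PreprocessParams()
    processed = [preprocess_recording(rec, params) for rec in epochs]
    for rec, row in zip(processed, manifest.itertuples()):
        write_epoch_csv(rec, COHORT / row.path.replace(".csv", "_proc.csv"))
    report = exclusion_report(processed)
    RESULTS.mkdir(exist_ok=True)
    report.to_csv(RESULTS / "exclusion_report.csv", index=False)
    print(f"preprocessed {len(processed)} epochs to {params.target_fs:g} Hz, "
          f"band {params.band[0]:g}-{params.band[1]:g} Hz")
    print(f"excluded epochs: {int(report['excluded'].sum())} "
          f"(mean flagged fraction {report['flagged_fraction'].mean():.4f})")


if __name__ == "__main__":
    main()
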