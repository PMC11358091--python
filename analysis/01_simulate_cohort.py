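"""Generate a demo paired cohort and write it to disk as CSV epochs.

Writes a reduced cohort (4 subjects x 2 conditions x 1 day x 4 epochs;
the full study design is 10 x 2 x 5 x 8) under scratch/demo_cohort/
with a manifest, and prints what was generated. Downstream scripts
(02-05) read this cohort; 06 runs the full pipeline in memory.
"""

from pathlib import Path

from ecognet import SynthConfig
from ecognet.recording import read_manifest
from ecognet.synth import scaled_config, write_cohort

OUT = Path(__file__).resolve().parent.parent / "scratch" / "demo_cohort"


def main():
    config = scaled_config(SynthConfig(seed=2024), n_subjects=4, n_days=1,
                           epochs_per_day=4)
    manifest_path = write_cohort(config, OUT)
    manifest = read_manifest(manifest_path)
    print(f"wrote {len(manifest)} epochs ({config.n_subjects} subjects x "
          f"2 conditions x {config.epochs_per_condition} epochs) to {OUT}")
    print(f"epoch shape: 10 channels x {config.n_epoch_samples} samples "
          f"at {config.fs:g} Hz")
    print(manifest.head(4).to_string(index=False))


if __name__ == "__main__":
    main()
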