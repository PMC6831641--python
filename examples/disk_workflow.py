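"""Round-trip a dataset through the on-disk format and the CLI-style fit.

Experimental users arrive with two-column text spectra (frequency,
intensity) — one file per titration point — plus the concentrations.
This example writes a synthetic dataset in exactly that layout, reads it
back, and fits it, mirroring `titrshape simulate` / `titrshape fit`.
"""

import tempfile
from pathlib import Path

from titrshape import FitConfig, fit_model, read_series, write_series
from titrshape.fixtures import two_state_dataset

with tempfile.TemporaryDirectory() as tmp:
    dataset_dir = Path(tmp) / "titration"
    paths = write_series(two_state_dataset(koff=5.0, seed=1), dataset_dir)
    print(f"wrote {len(paths)} spectra, e.g. {paths[0].name}:")
    print("  " + paths[0].read_text().splitlines()[0])

    data = read_series(dataset_dir)
    print(f"\nread back {len(data)} resonance(s), "
          f"{len(data[0])} titration points, Ptotal = {data[0].ptotal:g} uM")

    result = fit_model(data, FitConfig.two_state(n_starts=3, seed=0, snr=50.0))
    print("\nfitted parameters (true kd=10, koff=5):")
    for name, value in result.params.items():
        print(f"  {name:5s} = {value:7.3f}")

# The same run from a shell:
#   titrshape simulate --model 2state --defaults --out titration --seed 1
#   titrshape fit titration --model 2state --out results
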