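"""Generate a synthetic calibration-references CSV.

Produces phasor-phase readouts for a dilution-series-like set of
permittivities using the built-in forward model, and writes a CSV that
``dielmap calibrate`` can consume:

    python examples/make_references.py refs.csv
    dielmap calibrate --references refs.csv --out model.json
"""

import sys

import numpy as np

from dielmap import ForwardModel, generate_reference_set
from dielmap.io import write_references_csv


def main(out_path: str = "references.csv") -> None:
    model = ForwardModel()
    epsilons = np.linspace(2.0, 80.0, 21)
    refs = generate_reference_set(epsilons, model, noise_sd=0.5, seed=0)
    write_references_csv(out_path, refs)
    print(f"wrote {len(refs)} references to {out_path}")


if __name__ == "__main__":
    main(*sys.argv[1:])
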