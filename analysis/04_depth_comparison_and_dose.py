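"""Compare distributed isotropic emission against a directed beam in depth,
and compute the clinical light dose.

Both models share the attenuation coefficient and are normalized at the
first depth; the directed comparator is the same power concentrated at one
point (Beer-Lambert decay plus inverse-square dispersion). Writes
results/depth_profiles.csv.
"""
import argparse
from pathlib import Path

import numpy as np

from mnphotodose import DoseParams, EmitterDisk, compare_models, pdt_dose


def main() -> None:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--radius", type=float, default=3.0, help="disk radius R")
    p.add_argument("--alpha", type=float, default=0.3, help="attenuation (1/length)")
    p.add_argument("--out", default="results/depth_profiles.csv")
    args = p.parse_args()

    disk = EmitterDisk(R=args.radius, alpha=args.alpha)
    res = compare_models(disk, np.linspace(1.0, 5.0, 50))
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    res.to_frame().to_csv(args.out, index=False)
    retained = res.disk_profile.intensities[-1] / res.beam_profile.intensities[-1]
    print(
        f"fractional attenuation over the grid: disk {res.attenuation_disk:.3f} "
        f"vs directed beam {res.attenuation_beam:.3f}; at the deepest point the "
        f"distributed source retains {retained:.1f}x the beam's normalized "
        f"intensity (reference figure for direct coupling: "
        f"~{res.reference_fractional_change:.0%}, parameters unstated)"
    )
    dose = pdt_dose(DoseParams(125.0, 20 * 60.0))
    print(f"clinical exposure 125 mW/cm2 x 20 min = {dose:g} J/cm2")


if __name__ == "__main__":
    main()
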