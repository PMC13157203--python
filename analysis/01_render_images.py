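"""Render the synthetic angle set emulating the laser-lit array photographs.

Writes one 8-bit RGB PNG per camera angle (0, 24, 31, 57, 77 deg) plus a
manifest with the ground-truth gap/tip intensities, under results/renders/.
"""
import argparse

from mnphotodose import RenderSpec, render_angle_set


def main() -> None:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--out-dir", default="results/renders")
    args = p.parse_args()

    spec = RenderSpec(seed=args.seed)
    images = render_angle_set(spec, out_dir=args.out_dir)
    print(f"rendered {len(images)} angles into {args.out_dir}")
    for img in images:
        print(
            f"  {img.angle_deg:5.1f} deg  {img.pixels.shape[1]:4d}x{img.pixels.shape[0]} px  "
            f"gap={img.ground_truth['gap']:6.1f}  tip={img.ground_truth['tip']:5.1f}  "
            f"({img.um_per_px:.2f} um/px de-projected)"
        )
    print(
        "note: the between-tip transmission falls steeply with angle while "
        "tip scattering is angle-invariant; at 77 deg adjacent tip columns "
        "nearly merge."
    )


if __name__ == "__main__":
    main()
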