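"""Estimate tissue stiffness from the simulated AFM force maps.

For each map: detect the contact point of every curve, convert to
force-indentation, fit the spherical Hertz model for the elastic modulus,
average accepted fits, and normalize by the tumour-cell count on the
scanned area.  Writes results/afm_summary.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ecmech import io
from ecmech.afm import map_mean_modulus, normalize_by_cell_count
from ecmech.synthetic import SyntheticConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--out", type=Path, default=Path("results/afm_summary.csv"))
    parser.add_argument("--R", type=float, default=20e-9, help="tip radius, m")
    args = parser.parse_args()
    cfg = SyntheticConfig()

    rows = []
    for group, cells in zip(cfg.groups, cfg.cell_counts):
        manifest = args.indir / f"afm_{group}" / "manifest.csv"
        fmap = io.read_force_map(manifest, k=cfg.k, R=args.R, nu=cfg.nu)
        summary = map_mean_modulus(fmap)
        norm = normalize_by_cell_count(summary.mean_E, cells)
        rows.append(
            {"map": group, "mean_E_kPa": summary.mean_E / 1e3,
             "n_fitted": summary.n_fitted, "n_rejected": summary.n_rejected,
             "cell_count": cells, "normalized_E_kPa_per_cell": norm / 1e3}
        )
        print(f"{group}: mean E {summary.mean_E / 1e3:.2f} kPa "
              f"({summary.n_fitted} fits, {summary.n_rejected} rejected), "
              f"{norm / 1e3:.3f} kPa/cell over {cells} cells")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    io.write_table(pd.DataFrame(rows), args.out)
    print(f"summary written to {args.out}")


if __name__ == "__main__":
    main()
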