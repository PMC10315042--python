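"""Generate the full synthetic input bundle for the downstream analyses.

Writes, under results/synthetic/: per-fiber angle tables for a disordered
(PA-like) and an aligned (CXPA-like) cohort, one soft and one stiff AFM
force map with manifests, and a two-group collagen assay table.  Every
later script reads these files, so the whole pipeline is exercised through
the same CSV dialects real inputs would use.
"""

import argparse
from pathlib import Path

from ecmech import io
from ecmech.synthetic import (
    SyntheticConfig,
    noise_for_snr,
    simulate_collagen_assay,
    simulate_fiber_cohort,
    simulate_force_map,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = parser.parse_args()
    cfg = SyntheticConfig(seed=args.seed)
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    fields = simulate_fiber_cohort(
        cfg.n_cases_per_group, cfg.kappa_low, cfg.groups[0], cfg.seed + 1
    ) + simulate_fiber_cohort(
        cfg.n_cases_per_group, cfg.kappa_high, cfg.groups[1], cfg.seed + 2
    )
    io.write_angles(fields, out / "angles.csv", seed=cfg.seed, config=cfg)
    print(f"angles.csv: {len(fields)} fields, "
          f"{cfg.n_cases_per_group} cases per group x {cfg.n_fields} fields")

    for label, e_true, sub in ((cfg.groups[0], cfg.E_soft, 3), (cfg.groups[1], cfg.E_stiff, 4)):
        fmap, _ = simulate_force_map(
            e_true,
            shape=cfg.map_shape,
            E_sigma_log=cfg.E_sigma_log,
            seed=cfg.seed + sub,
            label=label,
            n_points=cfg.n_points,
            noise_sd=noise_for_snr(
                e_true, cfg.snr, nu=cfg.nu, R=cfg.R, max_indentation=cfg.max_indentation
            ),
            contact_offset=cfg.contact_offset,
            max_indentation=cfg.max_indentation,
            k=cfg.k,
            R=cfg.R,
            nu=cfg.nu,
        )
        manifest = io.write_force_map(fmap, out / f"afm_{label}", seed=cfg.seed, config=cfg)
        print(f"{manifest}: {cfg.map_shape[0]}x{cfg.map_shape[1]} map, "
              f"median E {e_true / 1e3:g} kPa at SNR {cfg.snr:g}")

    records = []
    for group, total, frac, sub in (
        (cfg.groups[0], cfg.collagen_total[0], cfg.collagen_soluble_fraction[0], 6),
        (cfg.groups[1], cfg.collagen_total[1], cfg.collagen_soluble_fraction[1], 7),
    ):
        records += simulate_collagen_assay(
            total, frac, cfg.collagen_noise, cfg.n_collagen, cfg.seed + sub,
            group=group, sample_prefix=group.lower(),
        )
    io.write_collagen(records, out / "collagen.csv", seed=cfg.seed, config=cfg)
    print(f"collagen.csv: {len(records)} samples "
          f"({cfg.n_collagen} per group)")


if __name__ == "__main__":
    main()
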