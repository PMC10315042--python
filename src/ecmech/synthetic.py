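"""Synthetic inputs with the statistical structure each analysis assumes.

No public dataset accompanies this kind of study (angle tables, raw AFM
curves and pathologist scores are rarely deposited), so every analysis
stage in this package is exercisable on simulated inputs with known ground
truth:

* fiber angles from an *axial* von Mises distribution (sample the doubled
  angle 2*theta from a von Mises with concentration kappa, halve, reduce
  mod 180) — the standard treatment of undirected orientations;
* raw AFM force curves from the spherical Hertz forward model with a flat
  pre-contact baseline, a contact-point offset along the piezo axis (so
  contact detection is non-trivially exercised) and additive Gaussian
  force noise;
* dichotomized IHC cohorts as independent binomial draws per group;
* collagen assay records with a set soluble fraction and truncated
  Gaussian noise.

``KAPPA_RANDOM`` and ``KAPPA_ALIGNED`` are frozen concentrations for the
two alignment regimes seen in salivary tumour sections: disordered
(benign-like, expected field AI ~ 0.54 under the 20-fiber protocol) and
aligned (carcinoma-like, expected AI ~ 0.75; found once by bisection on
the Monte-Carlo expectation).  Every simulator takes an explicit seed or
Generator; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .afm import ForceCurve, ForceMap, hertz_forward
from .fibers import FiberField
from .histology import CollagenAssayRecord, ContingencyTable2x2

__all__ = [
    "KAPPA_RANDOM",
    "KAPPA_ALIGNED",
    "SyntheticConfig",
    "SimulatedCurve",
    "noise_for_snr",
    "sample_axial_angles",
    "simulate_fiber_cohort",
    "simulate_force_curve",
    "simulate_force_map",
    "simulate_ihc_cohort",
    "simulate_collagen_assay",
]

#: concentration of the disordered (benign-like) fiber regime: uniform axial
KAPPA_RANDOM = 0.0
#: concentration of the aligned (carcinoma-like) regime; bisected once so the
#: expected field AI under the cohort generator's conditions (20 fibers per
#: field, dominant direction central in the angular reference) is 0.748
KAPPA_ALIGNED = 1.11


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SyntheticConfig:
    """Study-level parameters for the end-to-end synthetic run.

    Defaults mirror the measurement protocol this package models: 3 fields
    per case and 20 fibers per field for alignment; two alignment regimes
    (kappa 0 vs 1.09) at 3 cases per group; a 5 kPa (soft, benign-like) vs
    50 kPa (stiff, carcinoma-like) modulus contrast — the same contrast the
    hydrogel mimicry experiments use; IHC cohorts of 14 vs 14 with
    high-expression probabilities at the published COL1A1 margins (4/14 vs
    11/14); and collagen assays of 5 samples per group.
    """

    seed: int = 0
    # fiber alignment
    n_cases_per_group: int = 3
    n_fields: int = 3
    fibers_per_field: int = 20
    kappa_low: float = KAPPA_RANDOM
    kappa_high: float = KAPPA_ALIGNED
    # AFM
    E_soft: float = 5e3  # Pa
    E_stiff: float = 50e3  # Pa
    E_sigma_log: float = 0.2  # lognormal spread of per-cell moduli
    map_shape: tuple[int, int] = (8, 8)
    n_points: int = 150
    snr: float = 20.0  # RMS Hertz signal / force-noise sd, per map
    contact_offset: float = 200e-9  # m
    max_indentation: float = 100e-9  # m
    k: float = 5.0  # N/m
    R: float = 20e-9  # m
    nu: float = 0.5
    cell_counts: tuple[int, int] = (25, 12)  # cells on the scanned area
    # IHC
    group_sizes: tuple[int, int] = (14, 14)
    p_high: tuple[float, float] = (4 / 14, 11 / 14)
    # collagen
    n_collagen: int = 5
    collagen_total: tuple[float, float] = (8.0, 12.0)  # ug/mg tissue
    collagen_soluble_fraction: tuple[float, float] = (0.55, 0.30)
    collagen_noise: float = 0.5
    groups: tuple[str, str] = ("PA", "CXPA")


def sample_axial_angles(n: int, mode_angle_deg: float, concentration: float, seed) -> np.ndarray:
    """Draw n axial fiber angles (degrees in [0, 180)) around a mode.

    The doubled angle 2*theta is von Mises distributed with mean direction
    2*mode and concentration kappa; halving and reducing mod 180 yields a
    180-degree-periodic (axial) sample.  kappa = 0 is uniform on [0, 180).
    """
    if n < 1:
        raise ValueError(f"need at least one angle, got n={n}")
    if concentration < 0:
        raise ValueError(f"concentration must be non-negative, got {concentration}")
    rng = _rng(seed)
    doubled = rng.vonmises(np.radians(2.0 * mode_angle_deg), concentration, size=n)
    return (np.degrees(doubled) / 2.0) % 180.0


def simulate_fiber_cohort(
    n_cases: int,
    concentration: float,
    group: str,
    seed,
    *,
    n_fields: int = 3,
    fibers_per_field: int = 20,
    mode_range: tuple[float, float] = (45.0, 135.0),
    case_prefix: str | None = None,
) -> list[FiberField]:
    """Simulate a group of cases, each with several measured fields.

    Each field gets its own dominant direction, drawn uniformly from
    ``mode_range``.  The default keeps the dominant orientation away from
    the 0/180 wrap of the angular reference: the alignment index uses a
    linear median, which under-scores fields whose fiber tract straddles
    the horizontal reference line, so measurements (and their emulation
    here) reference angles with the tract roughly central.  Set
    ``mode_range=(0, 180)`` to simulate arbitrarily referenced fields.
    """
    rng = _rng(seed)
    prefix = case_prefix if case_prefix is not None else group
    fields = []
    for c in range(n_cases):
        for f in range(n_fields):
            mode = float(rng.uniform(*mode_range))
            angles = sample_axial_angles(fibers_per_field, mode, concentration, rng)
            fields.append(
                FiberField(
                    case_id=f"{prefix}{c + 1:02d}",
                    group=group,
                    field_id=f"f{f + 1}",
                    angles_deg=angles,
                )
            )
    return fields


@dataclass
class SimulatedCurve:
    """A simulated raw curve plus its ground truth."""

    curve: ForceCurve
    contact_index: int
    E_true: float


def noise_for_snr(
    E_true: float,
    snr: float,
    *,
    nu: float = 0.5,
    R: float = 20e-9,
    max_indentation: float = 100e-9,
) -> float:
    """Force-noise sd (N) giving a target signal-to-noise ratio.

    SNR is defined the standard way, as RMS signal over noise sd; for a
    Hertz segment sampled on a linear ramp to ``max_indentation`` the RMS
    force is half the peak force, so the returned sd is
    F_peak / (2 * snr).
    """
    if not snr > 0:
        raise ValueError(f"SNR must be positive, got {snr}")
    peak = hertz_forward(E_true, nu, R, max_indentation)
    return peak / (2.0 * snr)


def simulate_force_curve(
    E_true: float,
    *,
    nu: float = 0.5,
    R: float = 20e-9,
    k: float = 5.0,
    contact_offset: float = 200e-9,
    noise_sd: float = 0.0,
    n_points: int = 200,
    max_indentation: float = 100e-9,
    seed=0,
) -> SimulatedCurve:
    """Simulate one raw piezo-deflection curve from the Hertz forward model.

    The piezo extends on a uniform ramp (as a real triangle-wave drive
    does) crossing the sample surface at ``contact_offset``, which is
    snapped onto the sample grid so ground truth is well defined.  Past
    contact the indentation solves the force balance

        delta + F(delta) / k = z - z_contact

    (piezo travel splits between indentation and cantilever bending),
    found per sample by Newton iteration on this monotone equation.
    Gaussian noise of sd ``noise_sd`` (N) is added to the force at every
    sample; deflection is force / k throughout.
    """
    if E_true < 0:
        raise ValueError(f"modulus must be non-negative, got {E_true}")
    if not 0 <= nu < 1:
        raise ValueError(f"Poisson ratio must be in [0, 1), got {nu}")
    if not (R > 0 and k > 0):
        raise ValueError("tip radius and spring constant must be positive")
    if not contact_offset > 0:
        raise ValueError("contact offset must be positive")
    if noise_sd < 0:
        raise ValueError(f"noise sd must be non-negative, got {noise_sd}")
    if n_points < 10:
        raise ValueError("need at least 10 samples")
    rng = _rng(seed)

    peak = hertz_forward(E_true, nu, R, max_indentation)
    travel = contact_offset + max_indentation + peak / k
    spacing = travel / (n_points - 1)
    n_pre = int(round(contact_offset / spacing))
    n_pre = min(max(n_pre, 1), n_points - 5)
    z = (np.arange(n_points) - n_pre) * spacing + contact_offset

    # Newton solve of g(d) = d + F(d)/k - (z - zc) = 0 per post-contact sample
    zpost = z[n_pre:] - contact_offset
    c = (4.0 / 3.0) * E_true / (1.0 - nu**2) * np.sqrt(R)
    delta = zpost.copy()
    for _ in range(60):
        g = delta + c * delta**1.5 / k - zpost
        step = g / (1.0 + 1.5 * c * np.sqrt(delta) / k)
        delta = np.maximum(delta - step, 0.0)
        if np.max(np.abs(g)) < 1e-24 + 1e-15 * np.max(zpost):
            break
    f_post = hertz_forward(E_true, nu, R, delta)
    force_true = np.concatenate([np.zeros(n_pre), f_post])
    force = force_true + rng.normal(0.0, noise_sd, size=n_points) if noise_sd > 0 else force_true
    curve = ForceCurve(piezo_z=z, deflection=force / k, k=k, R=R, nu=nu)
    return SimulatedCurve(curve=curve, contact_index=n_pre, E_true=E_true)


def simulate_force_map(
    E_true,
    *,
    shape: tuple[int, int] = (50, 50),
    E_sigma_log: float = 0.0,
    seed=0,
    label: str = "",
    scan_size_um: tuple[float, float] = (10.0, 10.0),
    **curve_kwargs,
) -> tuple[ForceMap, np.ndarray]:
    """Simulate a force map; per-cell moduli are lognormal around E_true.

    ``E_true`` may be a scalar (the median of a lognormal with log-sd
    ``E_sigma_log``; sigma 0 means constant) or an array of per-cell moduli
    of the map's shape.  Returns the map and the ground-truth modulus grid.
    Remaining keyword arguments are forwarded to ``simulate_force_curve``.
    """
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {shape}")
    rng = _rng(seed)
    E_arr = np.asarray(E_true, dtype=float)
    if E_arr.ndim == 0:
        if E_sigma_log > 0:
            E_grid = float(E_arr) * np.exp(rng.normal(0.0, E_sigma_log, size=(rows, cols)))
        else:
            E_grid = np.full((rows, cols), float(E_arr))
    else:
        if E_arr.shape != (rows, cols):
            raise ValueError(f"modulus grid shape {E_arr.shape} does not match {shape}")
        E_grid = E_arr
    grid = [
        [simulate_force_curve(E_grid[r, c], seed=rng, **curve_kwargs).curve for c in range(cols)]
        for r in range(rows)
    ]
    return ForceMap(curves=grid, scan_size_um=scan_size_um, label=label), E_grid


def simulate_ihc_cohort(
    n_a: int,
    n_b: int,
    p_high_a: float,
    p_high_b: float,
    seed,
    *,
    groups: tuple[str, str] = ("PA", "CXPA"),
) -> ContingencyTable2x2:
    """Binomial low/high counts for two IHC cohorts as a 2x2 table."""
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be positive")
    for p in (p_high_a, p_high_b):
        if not 0 <= p <= 1:
            raise ValueError(f"probability {p} outside [0, 1]")
    rng = _rng(seed)
    high_a = int(rng.binomial(n_a, p_high_a))
    high_b = int(rng.binomial(n_b, p_high_b))
    return ContingencyTable2x2(
        a=n_a - high_a,
        b=high_a,
        c=n_b - high_b,
        d=high_b,
        group_a=groups[0],
        group_b=groups[1],
    )


def simulate_collagen_assay(
    total_mean: float,
    soluble_fraction: float,
    noise_sd: float,
    n: int,
    seed,
    *,
    group: str = "",
    sample_prefix: str = "s",
) -> list[CollagenAssayRecord]:
    """Simulate collagen assay records with a set soluble fraction.

    Totals are Gaussian around ``total_mean``; soluble amounts are Gaussian
    around ``soluble_fraction * total`` and truncated into [0, total] so
    every record satisfies the assay's conservation constraint.
    """
    if not total_mean > 0:
        raise ValueError(f"mean total collagen must be positive, got {total_mean}")
    if not 0 <= soluble_fraction <= 1:
        raise ValueError(f"soluble fraction {soluble_fraction} outside [0, 1]")
    if noise_sd < 0 or n < 1:
        raise ValueError("noise sd must be >= 0 and n >= 1")
    rng = _rng(seed)
    records = []
    for i in range(n):
        total = max(float(rng.normal(total_mean, noise_sd)), 1e-9)
        soluble = float(np.clip(rng.normal(soluble_fraction * total, noise_sd), 0.0, total))
        records.append(
            CollagenAssayRecord(
                sample_id=f"{sample_prefix}{i + 1:02d}",
                group=group,
                total=total,
                soluble=soluble,
            )
        )
    return records
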