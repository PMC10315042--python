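"""AFM force-curve processing and Hertz-model stiffness estimation.

An AFM force map scans a grid (default 50 x 50 over 10 x 10 um) of
force-indentation curves across an ECM-rich tissue region.  Each raw curve
records cantilever deflection d (m) against piezo extension z (m).  With
spring constant k the force is F = k * (d - d_baseline), and the sample
indentation is

    delta = (z - z_contact) - (d - d_baseline)

i.e. piezo travel past contact minus the part taken up by cantilever
bending.  Post-contact force follows the spherical-indenter Hertz model

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)

with elastic (Young's) modulus E (Pa), Poisson ratio nu (0.5 for an
incompressible sample), and tip radius R (m).  E enters linearly, so the
least-squares estimate given the contact point is the closed-form slope of
F on (4/3)(1-nu^2)^-1 sqrt(R) delta^(3/2); the contact point itself is found
by a grid search minimizing the total squared error of a two-piece model
(flat baseline before contact, Hertz fit after).

Per-map stiffness is the unweighted mean modulus over accepted fits;
curves whose relative RMS residual exceeds a threshold, or that show no
contact at all, are rejected and counted.  All quantities are SI internally
(m, N, Pa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ForceCurve",
    "IndentationCurve",
    "ForceMap",
    "HertzFit",
    "StiffnessSummary",
    "NoContactError",
    "hertz_forward",
    "to_indentation",
    "find_contact_point",
    "fit_hertz",
    "analyze_curve",
    "map_mean_modulus",
    "normalize_by_cell_count",
    "DEFAULT_SPRING_CONSTANT",
    "DEFAULT_POISSON_RATIO",
    "DEFAULT_REL_RESIDUAL_MAX",
]

#: cantilever spring constant, N/m (typical stiff cantilever for tissue)
DEFAULT_SPRING_CONSTANT = 5.0
#: Poisson ratio for an incompressible sample
DEFAULT_POISSON_RATIO = 0.5
#: reject fits with RMS residual > this fraction of the peak force
DEFAULT_REL_RESIDUAL_MAX = 0.2


class NoContactError(ValueError):
    """Raised when a curve shows no detectable tip-sample contact."""


def _check_probe(k: float, R: float, nu: float) -> None:
    if not k > 0:
        raise ValueError(f"spring constant must be positive, got {k}")
    if not R > 0:
        raise ValueError(f"tip radius must be positive, got {R}")
    if not 0 <= nu < 1:
        raise ValueError(f"Poisson ratio must be in [0, 1), got {nu}")


@dataclass
class ForceCurve:
    """Raw piezo-deflection samples plus probe constants.

    ``piezo_z`` must be strictly increasing; both arrays are in metres.
    """

    piezo_z: np.ndarray = field(repr=False)
    deflection: np.ndarray = field(repr=False)
    k: float = DEFAULT_SPRING_CONSTANT
    R: float = 20e-9
    nu: float = DEFAULT_POISSON_RATIO

    def __post_init__(self):
        z = np.asarray(self.piezo_z, dtype=float)
        d = np.asarray(self.deflection, dtype=float)
        if z.shape != d.shape or z.ndim != 1:
            raise ValueError("piezo_z and deflection must be 1-D and equal length")
        if z.size < 10:
            raise ValueError("a force curve needs at least 10 samples")
        if not np.all(np.diff(z) > 0):
            raise ValueError("piezo_z must be strictly increasing")
        _check_probe(self.k, self.R, self.nu)
        self.piezo_z, self.deflection = z, d

    def __len__(self) -> int:
        return self.piezo_z.size


@dataclass
class IndentationCurve:
    """Force against sample indentation, after contact-point referencing."""

    delta: np.ndarray = field(repr=False)  # m, clipped at 0 pre-contact
    force: np.ndarray = field(repr=False)  # N, baseline-subtracted
    contact_index: int


@dataclass
class ForceMap:
    """Rectangular grid of force curves over one scanned region."""

    curves: list[list[ForceCurve]]
    scan_size_um: tuple[float, float] = (10.0, 10.0)
    label: str = ""

    def __post_init__(self):
        if not self.curves or not self.curves[0]:
            raise ValueError("force map grid must be non-empty")
        ncol = len(self.curves[0])
        if any(len(row) != ncol for row in self.curves):
            raise ValueError("force map grid must be rectangular")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.curves), len(self.curves[0])

    def __iter__(self):
        for row in self.curves:
            yield from row


@dataclass
class HertzFit:
    """Result of a Hertz fit on one indentation curve."""

    E: float  # Pa, >= 0
    rms_residual: float  # N
    rel_residual: float  # rms residual / max |force|
    n_points: int  # post-contact points used
    accepted: bool


@dataclass
class StiffnessSummary:
    """Per-map stiffness aggregate."""

    mean_E: float  # Pa, over accepted fits
    n_fitted: int
    n_rejected: int
    E_values: np.ndarray = field(repr=False)
    normalized_E: float | None = None  # Pa per cell
    cell_count: int | None = None
    label: str = ""


def hertz_forward(E: float, nu: float, R: float, delta) -> np.ndarray | float:
    """Hertz force for a spherical indenter: (4/3) E/(1-nu^2) sqrt(R) delta^1.5."""
    if not 0 <= nu < 1:
        raise ValueError(f"Poisson ratio must be in [0, 1), got {nu}")
    if E < 0 or R < 0:
        raise ValueError("modulus and tip radius must be non-negative")
    d = np.maximum(np.asarray(delta, dtype=float), 0.0)
    out = (4.0 / 3.0) * E / (1.0 - nu**2) * np.sqrt(R) * d**1.5
    return float(out) if np.isscalar(delta) else out


def to_indentation(curve: ForceCurve, contact_index: int) -> IndentationCurve:
    """Convert a raw curve to force-indentation given the contact sample.

    Baseline deflection is the mean over pre-contact samples; force is
    k * (deflection - baseline); indentation is piezo travel past contact
    minus cantilever bending, clipped at zero before contact.
    """
    n = len(curve)
    if not 0 < contact_index < n - 1:
        raise ValueError(
            f"contact index {contact_index} leaves no pre-contact baseline "
            f"or no post-contact data (curve has {n} samples)"
        )
    baseline = float(np.mean(curve.deflection[:contact_index]))
    bent = curve.deflection - baseline
    force = curve.k * bent
    delta = (curve.piezo_z - curve.piezo_z[contact_index]) - bent
    delta = np.maximum(delta, 0.0)  # pre-contact travel carries no indentation
    return IndentationCurve(delta=delta, force=force, contact_index=contact_index)


def _ls_modulus(delta_post: np.ndarray, force_post: np.ndarray, nu: float, R: float) -> float:
    """Closed-form least-squares E >= 0 for F = c(E) * delta^1.5."""
    x = (4.0 / 3.0) / (1.0 - nu**2) * np.sqrt(R) * delta_post**1.5
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        return 0.0
    return max(float(np.dot(x, force_post)) / sxx, 0.0)


def find_contact_point(
    curve: ForceCurve,
    *,
    search_fraction: tuple[float, float] = (0.05, 0.95),
    min_post_points: int = 5,
    noise_factor: float = 3.0,
) -> int:
    """Locate the tip-sample contact sample by two-piece model selection.

    Every candidate index in the middle of the curve (``search_fraction``
    bounds, guaranteeing a baseline window and a fit window) is scored by
    the total squared error of: flat baseline before the candidate, Hertz
    fit after it.  The minimizer is returned.

    Raises
    ------
    NoContactError
        If no candidate admits a valid fit, or the best fit's predicted
        force rise does not exceed ``noise_factor`` times the baseline
        noise (covers flat and pure-noise curves).
    """
    n = len(curve)
    lo = max(int(np.ceil(search_fraction[0] * n)), 2)
    hi = min(int(np.floor(search_fraction[1] * n)), n - min_post_points)
    if hi <= lo:
        raise NoContactError("curve too short for contact search")

    z, d, k = curve.piezo_z, curve.deflection, curve.k
    best_sse, best_idx, best = np.inf, None, None
    for i in range(lo, hi):
        baseline = np.mean(d[:i])
        bent = d - baseline
        force = k * bent
        delta = (z - z[i]) - bent
        post = slice(i, n)
        dpost = np.maximum(delta[post], 0.0)
        E = _ls_modulus(dpost, force[post], curve.nu, curve.R)
        fhat = hertz_forward(E, curve.nu, curve.R, dpost)
        sse = float(np.sum(force[:i] ** 2)) + float(np.sum((force[post] - fhat) ** 2))
        if sse < best_sse:
            best_sse, best_idx = sse, i
            best = (force, fhat, i)
    if best_idx is None:
        raise NoContactError("no candidate contact point admits a valid fit")

    force, fhat, i = best
    noise_sd = float(np.std(force[:i]))
    if fhat.size == 0 or float(np.max(fhat)) <= noise_factor * noise_sd:
        raise NoContactError("no post-contact force rise above baseline noise")
    return best_idx


def fit_hertz(
    ind: IndentationCurve,
    nu: float,
    R: float,
    *,
    rel_residual_max: float = DEFAULT_REL_RESIDUAL_MAX,
) -> HertzFit:
    """Least-squares Hertz modulus from a force-indentation curve.

    Uses post-contact points with positive indentation.  Because force is
    linear in E, ordinary least squares on delta^(3/2) is the exact
    minimizer of the squared residual; the estimate is clipped at zero.
    Fits whose RMS residual exceeds ``rel_residual_max`` times the peak
    force are flagged as rejected.
    """
    _check_probe(1.0, R, nu)
    post = slice(ind.contact_index, None)
    delta = np.maximum(ind.delta[post], 0.0)
    force = ind.force[post]
    mask = delta > 0
    if int(mask.sum()) < 5:
        raise ValueError("need at least 5 post-contact points with positive indentation")
    delta, force = delta[mask], force[mask]
    E = _ls_modulus(delta, force, nu, R)
    resid = force - hertz_forward(E, nu, R, delta)
    rms = float(np.sqrt(np.mean(resid**2)))
    fmax = float(np.max(np.abs(force)))
    rel = rms / fmax if fmax > 0 else (0.0 if rms == 0.0 else np.inf)
    return HertzFit(
        E=E,
        rms_residual=rms,
        rel_residual=rel,
        n_points=int(delta.size),
        accepted=rel <= rel_residual_max,
    )


def analyze_curve(
    curve: ForceCurve, *, rel_residual_max: float = DEFAULT_REL_RESIDUAL_MAX
) -> HertzFit:
    """Full single-curve pipeline: contact detection, referencing, Hertz fit."""
    idx = find_contact_point(curve)
    ind = to_indentation(curve, idx)
    return fit_hertz(ind, curve.nu, curve.R, rel_residual_max=rel_residual_max)


def map_mean_modulus(
    fmap: ForceMap,
    *,
    rel_residual_max: float = DEFAULT_REL_RESIDUAL_MAX,
    reject: bool = True,
) -> StiffnessSummary:
    """Mean E-modulus of a force map over accepted per-curve fits.

    Curves with no detectable contact, failed fits, or (when ``reject`` is
    on) excessive residuals are counted as rejected and excluded from the
    mean.
    """
    accepted, n_rejected = [], 0
    for curve in fmap:
        try:
            fit = analyze_curve(curve, rel_residual_max=rel_residual_max)
        except (NoContactError, ValueError):
            n_rejected += 1
            continue
        if reject and not fit.accepted:
            n_rejected += 1
            continue
        accepted.append(fit.E)
    if not accepted:
        raise ValueError(f"force map {fmap.label!r}: no curve produced an accepted fit")
    values = np.asarray(accepted)
    return StiffnessSummary(
        mean_E=float(values.mean()),
        n_fitted=len(accepted),
        n_rejected=n_rejected,
        E_values=values,
        label=fmap.label,
    )


def normalize_by_cell_count(mean_E: float, cell_count: int) -> float:
    """Normalize a mean modulus by the tumour-cell count on the scanned area.

    Returned in Pa per cell (the source protocol does not define a unit for
    this quantity; it is reported and labelled as Pa/cell throughout).
    """
    if cell_count < 1:
        raise ValueError(f"cell count must be a positive integer, got {cell_count}")
    if mean_E < 0:
        warnings.warn("negative mean modulus passed to normalization", stacklevel=2)
    return mean_E / cell_count
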