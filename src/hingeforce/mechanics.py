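"""Lever moment-equilibrium force amplification and its bench validation.

The glasses temple pivots about the hinge joint.  A force ``F_temple``
applied at the epidermis contact point, a lever arm ``L_temple`` from the
joint, is balanced at the hinge load cell, a much shorter arm ``L_hinge``
away, so moment equilibrium gives

    F_hinge = (L_temple / L_hinge) * F_temple

i.e. a purely geometric amplification factor ``L_temple / L_hinge``.  The
bench procedure that validates this pushes the temple with a linear stage in
small displacement steps while recording both load cells, then estimates the
factor as the slope of an ordinary least-squares fit of ``F_hinge`` against
``F_temple``.

The simulator here uses an ideal linear-elastic contact with additive
Gaussian measurement noise; hinge friction and the temple's own weight (real
bench error sources at very low force) are deliberately outside the model,
which is why simulated factors recover the geometric value exactly while a
physical bench reads slightly low.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class LeverGeometry:
    """Lever-arm lengths (mm) measured from the hinge joint.

    ``L_temple`` is the joint-to-epidermis contact distance and ``L_hinge``
    the joint-to-hinge-load-cell distance; the mechanism amplifies when the
    temple arm is the longer one (equal arms are the degenerate factor-1
    lever).
    """

    L_temple: float
    L_hinge: float

    def __post_init__(self) -> None:
        if self.L_temple <= 0 or self.L_hinge <= 0:
            raise ValueError("lever arm lengths must be positive")
        if self.L_temple < self.L_hinge:
            raise ValueError("L_temple must be at least L_hinge")


#: Default geometry: 69 mm temple arm and 9 mm hinge arm, giving the
#: theoretical amplification factor 69/9 = 7.67.
DEFAULT_GEOMETRY = LeverGeometry(L_temple=69.0, L_hinge=9.0)


@dataclass(frozen=True)
class BenchSweep:
    """Paired temple/hinge force measurements over a displacement sweep."""

    displacement: np.ndarray  # mm, strictly increasing
    F_temple: np.ndarray  # N
    F_hinge: np.ndarray  # N

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=float)
        ft = np.asarray(self.F_temple, dtype=float)
        fh = np.asarray(self.F_hinge, dtype=float)
        if not (len(d) == len(ft) == len(fh)):
            raise ValueError("displacement, F_temple, F_hinge must be equal length")
        if len(d) > 1 and not np.all(np.diff(d) > 0):
            raise ValueError("displacement must be strictly increasing")
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "F_temple", ft)
        object.__setattr__(self, "F_hinge", fh)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "displacement_mm": self.displacement,
                "F_temple_N": self.F_temple,
                "F_hinge_N": self.F_hinge,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BenchSweep":
        frame = pd.read_csv(path)
        return cls(
            displacement=frame["displacement_mm"].to_numpy(),
            F_temple=frame["F_temple_N"].to_numpy(),
            F_hinge=frame["F_hinge_N"].to_numpy(),
        )


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares line fit summary."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")


def amplification_factor(geom: LeverGeometry) -> float:
    """Theoretical hinge/temple force ratio from moment equilibrium."""
    return geom.L_temple / geom.L_hinge


def transmit_force(F_temple: float | np.ndarray, geom: LeverGeometry) -> float | np.ndarray:
    """Hinge force produced by a temple force under the ideal lever model."""
    F_temple = np.asarray(F_temple, dtype=float)
    if np.any(F_temple < 0):
        raise ValueError("F_temple must be non-negative")
    out = amplification_factor(geom) * F_temple
    return float(out) if out.ndim == 0 else out


def fit_line(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Least-squares line through (x, y) with R^2 and a two-sided slope test.

    The p-value is the t-test of zero slope, equivalent for one predictor to
    the regression F-test.  A perfectly flat response (constant y) is reported
    as slope 0 with R^2 = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    if np.ptp(y) == 0:
        return RegressionFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0)
    res = stats.linregress(x, y)
    # an exact line underflows the t-test p-value to 0; keep it in (0, 1]
    p = max(float(res.pvalue), np.finfo(float).tiny)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(float(res.rvalue) ** 2, 1.0),
        p_value=p,
    )


def estimate_amplification(sweep: BenchSweep) -> RegressionFit:
    """Experimental amplification factor: slope of F_hinge regressed on F_temple."""
    return fit_line(sweep.F_temple, sweep.F_hinge)


def simulate_bench(
    geom: LeverGeometry = DEFAULT_GEOMETRY,
    stiffness_temple: float = 0.44,
    n_steps: int = 100,
    step: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    contact_onset: float = 0.0,
) -> BenchSweep:
    """Simulate a displacement sweep of the bench apparatus.

    The temple contact is linear-elastic: past the contact-onset displacement
    ``d0``, the true temple force is ``stiffness_temple * (d - d0)`` (N, with
    stiffness in N/mm) and the true hinge force follows the lever model.
    Independent Gaussian noise of standard deviation ``noise_sd`` is added to
    each measured channel.  The default 0.05 mm step matches a 50 um
    micrometer stage resolution.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if n_steps < 3:
        raise ValueError("n_steps must be at least 3")
    rng = np.random.default_rng(seed)
    displacement = step * np.arange(1, n_steps + 1)
    f_temple_true = stiffness_temple * np.clip(displacement - contact_onset, 0.0, None)
    f_hinge_true = transmit_force(f_temple_true, geom)
    f_temple = f_temple_true + (rng.normal(0, noise_sd, n_steps) if noise_sd else 0.0)
    f_hinge = f_hinge_true + (rng.normal(0, noise_sd, n_steps) if noise_sd else 0.0)
    return BenchSweep(displacement=displacement, F_temple=f_temple, F_hinge=f_hinge)
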