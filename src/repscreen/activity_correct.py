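"""Activity correction: control regressions, adjusted indel frequency X,
and the corrected viability score v.

A guide's observed dropout (fold change FC) confounds two things: the
fitness effect of disrupting its target and the guide's cutting activity.
Because reporter editing is coupled to target editing within each cell,
cells that drop out take their edited reporters with them, so the observed
reporter indel frequency *underestimates* true cutting for depleted guides.
Two identities resolve this.  With ``v`` the relative viability of
edited cells and ``X`` the true edited fraction:

    FC        = (v - 1) * X + 1
    indel_obs = X * v / FC          (edited survivors over all survivors)

which invert exactly as

    X = 1 - FC + FC * indel_obs.

Negative-control guides calibrate two nuisance effects.  First, even
controls drop out slightly in proportion to their activity (DNA-damage
response to cutting itself); the regression of raw FC on observed indel
over controls extrapolates to ``FC0``, the fold change of a hypothetical
zero-activity guide, and every FC is normalised by it.  Second, the
regression of normalised FC on X over controls defines ``FC_v=1(X)``, the
fold change expected when target disruption is neutral.  The corrected
viability interpolates between the theoretical floor ``FC_v=0 = 1 - X``
and that ceiling:

    v = (FC_norm - (1 - X)) / (FC_v=1(X) - (1 - X)).

v is deliberately not clipped (enrichment gives v > 1).  At low X the
floor and ceiling converge and v amplifies FC noise, so guides below an
``x_min`` threshold are flagged unreliable rather than dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .library_io import GuideRecord, ROLE_NEGATIVE_CONTROL
from .screen_quant import GuideQuant

DEFAULT_X_MIN = 0.05
# X above which low-activity noise amplification is negligible; reported as
# a diagnostic annotation alongside the reliability flag
HIGH_CONFIDENCE_X = 0.44
DENOM_EPS = 1e-6


@dataclass(frozen=True)
class ControlFit:
    """The two negative-control regression lines.

    Regression 1, ``fc_raw ~ indel_obs``: intercept is ``fc0``, the fold
    change of a hypothetical zero-activity control; its slope estimates
    the DNA-damage-response fitness cost per unit editing.  Regression 2,
    ``fc_norm ~ X``: defines the neutral-viability line
    ``FC_v=1(X) = slope2 * X + intercept2``.
    """

    slope1: float
    intercept1: float
    slope2: float
    intercept2: float
    n_controls: int

    @property
    def fc0(self) -> float:
        return self.intercept1

    def fc_v1(self, x: float | np.ndarray) -> float | np.ndarray:
        """Expected fold change of a neutral (v = 1) guide with activity x."""
        return self.slope2 * x + self.intercept2

    def to_dict(self) -> dict:
        return {
            "fc0": self.fc0,
            "slope1": self.slope1,
            "intercept1": self.intercept1,
            "slope2": self.slope2,
            "intercept2": self.intercept2,
            "n_controls": self.n_controls,
        }


@dataclass(frozen=True)
class GuideMetrics:
    """Corrected per-guide metrics.

    ``x_adj`` is X clipped to [0, 1] (``x_raw`` keeps the unclipped value,
    ``x_clipped`` flags when they differ); ``v`` is NaN when undefined
    (no indel estimate, or degenerate denominator, flagged by
    ``v_defined``).  ``reliable`` marks ``x_adj >= x_min``.
    """

    guide_id: str
    gene: str
    role: str
    fc_raw: float
    fc_norm: float
    indel_obs: float
    x_raw: float
    x_adj: float
    x_clipped: bool
    v: float
    v_defined: bool
    reliable: bool
    high_confidence_x: bool


class ControlFitError(ValueError):
    """Raised when the negative-control regressions cannot be fit."""


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary least squares slope and intercept of y on x."""
    if np.ptp(x) == 0:
        raise ControlFitError("zero variance in regressor (controls span no indel range)")
    slope, intercept, *_ = stats.linregress(x, y)
    return float(slope), float(intercept)


def fit_controls(
    quants: Sequence[GuideQuant],
    library: Optional[Sequence[GuideRecord]] = None,
    control_genes: Optional[set[str]] = None,
) -> ControlFit:
    """Fit both control regressions from QC-passing negative controls.

    ``quants`` may be pre-restricted to controls; otherwise pass
    ``library`` so controls are selected by role (or, for libraries
    without explicit controls, by membership of ``control_genes``, a
    user-declared set of neutral genes).  Requires >= 3 controls with a
    defined indel estimate spanning a nonzero indel range.
    """
    ctrl = list(quants)
    if library is not None:
        roles = {r.guide_id: (r.role, r.gene) for r in library}
        def is_ctrl(q: GuideQuant) -> bool:
            role, gene = roles.get(q.guide_id, (None, None))
            if role == ROLE_NEGATIVE_CONTROL:
                return True
            return control_genes is not None and gene in control_genes
        ctrl = [q for q in ctrl if is_ctrl(q)]
    ctrl = [q for q in ctrl if q.qc_pass and not math.isnan(q.indel_obs)]
    if len(ctrl) < 3:
        raise ControlFitError(
            f"need >= 3 qc-passing negative controls with indel estimates, got {len(ctrl)}"
        )
    indel = np.array([q.indel_obs for q in ctrl])
    fc_raw = np.array([q.fc_raw for q in ctrl])
    slope1, intercept1 = _ols(indel, fc_raw)
    if intercept1 <= 0:
        raise ControlFitError(f"fitted FC0 = {intercept1:.4g} is not positive")
    fc_norm = fc_raw / intercept1
    x = 1.0 - fc_norm + fc_norm * indel
    slope2, intercept2 = _ols(x, fc_norm)
    return ControlFit(
        slope1=slope1,
        intercept1=intercept1,
        slope2=slope2,
        intercept2=intercept2,
        n_controls=len(ctrl),
    )


def normalize_fc(fc_raw: float, fit: ControlFit) -> float:
    """FC_norm = FC_raw / FC0."""
    if fit.fc0 <= 0:
        raise ValueError(f"FC0 must be positive, got {fit.fc0}")
    return fc_raw / fit.fc0


def compute_x(fc_norm: float, indel_obs: float) -> tuple[float, float, bool]:
    """Adjusted indel frequency X = 1 - FC_norm + FC_norm * indel_obs.

    Returns ``(x_raw, x_clipped_to_unit_interval, was_clipped)``.
    """
    x_raw = 1.0 - fc_norm + fc_norm * indel_obs
    x_adj = min(1.0, max(0.0, x_raw))
    return x_raw, x_adj, x_adj != x_raw


def compute_v(
    fc_norm: float,
    x: float,
    fit: ControlFit,
    x_min: float = DEFAULT_X_MIN,
    eps: float = DENOM_EPS,
) -> tuple[float, bool, bool]:
    """Corrected viability v = (FC_norm - (1-X)) / (FC_v=1(X) - (1-X)).

    Returns ``(v, defined, reliable)``.  ``defined`` is False (v = NaN)
    when the floor-to-ceiling denominator is within ``eps`` of zero;
    ``reliable`` is ``x >= x_min``.  v is not clipped.
    """
    if not 0.0 < x <= 1.0:
        raise ValueError(f"x must be in (0, 1], got {x}")
    denom = fit.fc_v1(x) - (1.0 - x)
    if abs(denom) < eps:
        return math.nan, False, x >= x_min
    return (fc_norm - (1.0 - x)) / denom, True, x >= x_min


def correct_screen(
    quants: Sequence[GuideQuant],
    library: Sequence[GuideRecord],
    x_min: float = DEFAULT_X_MIN,
    control_genes: Optional[set[str]] = None,
    fit: Optional[ControlFit] = None,
) -> tuple[list[GuideMetrics], ControlFit]:
    """Run the full correction over one replicate's quantification.

    Fits the control regressions (unless a prefitted ``fit`` is supplied,
    e.g. when pooling replicates), then computes FC_norm, X and v for
    every QC-passing guide, controls included.  Guides that fail QC or
    lack an indel estimate get NaN metrics with flags cleared.
    """
    by_id = {r.guide_id: r for r in library}
    missing = [q.guide_id for q in quants if q.guide_id not in by_id]
    if missing:
        raise ValueError(f"guides absent from library: {missing[:5]}")
    if fit is None:
        fit = fit_controls(quants, library=library, control_genes=control_genes)

    out = []
    for q in quants:
        rec = by_id[q.guide_id]
        if not q.qc_pass or math.isnan(q.indel_obs):
            out.append(
                GuideMetrics(
                    guide_id=q.guide_id, gene=rec.gene, role=rec.role,
                    fc_raw=q.fc_raw, fc_norm=math.nan, indel_obs=q.indel_obs,
                    x_raw=math.nan, x_adj=math.nan, x_clipped=False,
                    v=math.nan, v_defined=False, reliable=False,
                    high_confidence_x=False,
                )
            )
            continue
        fc_norm = normalize_fc(q.fc_raw, fit)
        x_raw, x_adj, clipped = compute_x(fc_norm, q.indel_obs)
        if x_adj > 0.0:
            v, defined, reliable = compute_v(fc_norm, x_adj, fit, x_min=x_min)
        else:
            v, defined, reliable = math.nan, False, False
        out.append(
            GuideMetrics(
                guide_id=q.guide_id, gene=rec.gene, role=rec.role,
                fc_raw=q.fc_raw, fc_norm=fc_norm, indel_obs=q.indel_obs,
                x_raw=x_raw, x_adj=x_adj, x_clipped=clipped,
                v=v, v_defined=defined, reliable=reliable,
                high_confidence_x=(x_adj >= HIGH_CONFIDENCE_X),
            )
        )
    return out, fit


def metrics_to_frame(metrics: Sequence[GuideMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                m.guide_id, m.gene, m.role, m.fc_raw, m.fc_norm, m.indel_obs,
                m.x_adj, m.v, m.reliable,
            )
            for m in metrics
        ],
        columns=[
            "guide_id", "gene", "role", "fc_raw", "fc_norm", "indel_obs",
            "x_adj", "v", "reliable",
        ],
    )


def write_metrics(
    metrics: Sequence[GuideMetrics],
    fit: ControlFit,
    tsv_path: str | Path,
    fit_json_path: Optional[str | Path] = None,
) -> None:
    metrics_to_frame(metrics).to_csv(tsv_path, sep="\t", index=False)
    if fit_json_path is not None:
        Path(fit_json_path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")
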