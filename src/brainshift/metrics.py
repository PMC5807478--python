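"""Marker-based validation statistics for displacement-field comparisons.

Given a measured and a simulated displacement vector per marker, three
error measures are computed:

* **EPE** (end-point error): Euclidean length of the vector difference.
* **AE** (angular error): angle between the two vectors.  The ``plain``
  variant is the 3D arccos of the normalized dot product, undefined when
  either vector vanishes (such markers are flagged and excluded from
  averages); the ``augmented`` optical-flow variant appends a unit
  component to both vectors first and is well defined everywhere.
* **ME** (magnitude error): ``|u_meas| - |u_sim|`` — signed, positive when
  the measurement is larger than the simulation.

Summaries report the average, standard error of the mean, and the
min/max values with the marker ids at which they occur.  Two
formulations are compared with a standard two-sample Student t test on
the per-marker errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "end_point_error",
    "angular_error",
    "magnitude_error",
    "ErrorReport",
    "summarize",
    "compare_models",
    "error_table",
]


def _as_vectors(u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != 3:
        raise ValueError("displacement vectors must have 3 components")
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement vectors must be finite")
    return u


def end_point_error(u_meas, u_sim):
    """Euclidean norm of ``u_meas - u_sim`` (symmetric in its arguments)."""
    a = _as_vectors(u_meas)
    b = _as_vectors(u_sim)
    return np.linalg.norm(a - b, axis=-1)


def angular_error(u_meas, u_sim, variant: str = "plain"):
    """Angle between measured and simulated vectors, rad, in ``[0, pi]``.

    ``plain`` returns NaN where either vector is zero (the caller is
    expected to exclude those; :func:`summarize` does and counts them).
    ``augmented`` appends a unit component to each vector, making the
    angle well defined at zero displacement.
    """
    a = _as_vectors(u_meas)
    b = _as_vectors(u_sim)
    if variant == "augmented":
        pad = np.ones(a.shape[:-1] + (1,))
        a = np.concatenate([a, pad], axis=-1)
        b = np.concatenate([b, pad], axis=-1)
    elif variant != "plain":
        raise ValueError(f"unknown AE variant {variant!r}")
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(denom > 0, np.einsum("...i,...i->...", a, b) / np.where(denom > 0, denom, 1.0), np.nan)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def magnitude_error(u_meas, u_sim):
    """Signed magnitude difference ``|u_meas| - |u_sim|``."""
    a = _as_vectors(u_meas)
    b = _as_vectors(u_sim)
    return np.linalg.norm(a, axis=-1) - np.linalg.norm(b, axis=-1)


@dataclass(frozen=True)
class ErrorReport:
    """Summary of one per-marker error sample.

    ``sem`` is ``sd / sqrt(n)`` (sample standard deviation, ddof = 1) and
    is NaN for a single marker.  ``min_id``/``max_id`` give the marker at
    which the extreme occurs (ties broken toward the lowest id).
    ``n_excluded`` counts markers dropped because the metric was
    undefined (zero vectors in the plain angular error).
    """

    metric: str
    avg: float
    sem: float
    min: float
    min_id: int
    max: float
    max_id: int
    n: int
    n_excluded: int = 0
    step_label: str = ""
    values: tuple = ()
    ids: tuple = ()


def summarize(errors, marker_ids=None, metric: str = "",
              step_label: str = "") -> ErrorReport:
    """Summarize per-marker errors into an :class:`ErrorReport`.

    NaN entries (undefined metric values) are excluded and counted.
    """
    errors = np.asarray(errors, dtype=float)
    if marker_ids is None:
        marker_ids = np.arange(1, len(errors) + 1)
    marker_ids = np.asarray(marker_ids)
    if errors.shape != marker_ids.shape:
        raise ValueError("errors and marker ids must align")
    keep = np.isfinite(errors)
    n_excluded = int((~keep).sum())
    errors = errors[keep]
    marker_ids = marker_ids[keep]
    n = len(errors)
    if n == 0:
        raise ValueError("no finite error values to summarize")
    # stable extreme selection: ties resolved toward the lowest marker id
    order = np.lexsort((marker_ids, errors))
    i_min = order[0]
    order_max = np.lexsort((marker_ids, -errors))
    i_max = order_max[0]
    sem = float(np.std(errors, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return ErrorReport(
        metric=metric,
        avg=float(np.mean(errors)),
        sem=sem,
        min=float(errors[i_min]),
        min_id=int(marker_ids[i_min]),
        max=float(errors[i_max]),
        max_id=int(marker_ids[i_max]),
        n=n,
        n_excluded=n_excluded,
        step_label=step_label,
        values=tuple(errors),
        ids=tuple(int(i) for i in marker_ids),
    )


def compare_models(report_a: ErrorReport, report_b: ErrorReport,
                   paired: bool = False):
    """Student two-sample t test on the per-marker errors of two reports.

    The default is the unpaired, pooled-variance (equal variance) test;
    ``paired=True`` uses the paired variant (requires identical marker
    sets).  Returns ``(t_statistic, p_value)``, two-sided.
    """
    a = np.asarray(report_a.values, dtype=float)
    b = np.asarray(report_b.values, dtype=float)
    if paired:
        if report_a.ids != report_b.ids:
            raise ValueError("paired test requires identical marker sets")
        t, p = stats.ttest_rel(a, b)
    else:
        if set(report_a.ids) != set(report_b.ids):
            raise ValueError("reports must cover the same marker set")
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def error_table(measured: pd.DataFrame, simulated: pd.DataFrame,
                ae_variant: str = "plain",
                me_absolute_extremes: bool = True) -> pd.DataFrame:
    """Per-step error summary table from two marker-trajectory frames.

    Both frames use the trajectory layout (``step``, ``pct_loss``,
    ``marker_id``, ``ux_mm``, ``uy_mm``, ``uz_mm``).  For each step and
    each metric the table reports avg, sem, min, min_id, max, max_id.
    The ME average is signed; its min/max are taken on absolute values by
    default (``me_absolute_extremes``).
    """
    cols = ["ux_mm", "uy_mm", "uz_mm"]
    out = []
    for step, grp_m in measured.groupby("step"):
        grp_s = simulated[simulated["step"] == step]
        merged = grp_m.merge(grp_s, on="marker_id", suffixes=("_meas", "_sim"))
        if len(merged) == 0:
            raise ValueError(f"no common markers at step {step}")
        um = merged[[c + "_meas" for c in cols]].to_numpy()
        us = merged[[c + "_sim" for c in cols]].to_numpy()
        ids = merged["marker_id"].to_numpy()
        label = str(merged["pct_loss_meas"].iloc[0]) if "pct_loss_meas" in merged else str(step)
        epe = summarize(end_point_error(um, us), ids, "EPE", label)
        ae_vals = angular_error(um, us, ae_variant)
        if np.all(~np.isfinite(ae_vals)):
            # every marker excluded (zero displacement at this step):
            # report an empty AE row rather than failing the whole table
            ae = ErrorReport(metric="AE", avg=np.nan, sem=np.nan,
                             min=np.nan, min_id=-1, max=np.nan, max_id=-1,
                             n=0, n_excluded=len(ae_vals), step_label=label)
        else:
            ae = summarize(ae_vals, ids, "AE", label)
        me_vals = magnitude_error(um, us)
        me = summarize(me_vals, ids, "ME", label)
        if me_absolute_extremes:
            me_abs = summarize(np.abs(me_vals), ids, "ME", label)
            me = ErrorReport(
                metric="ME", avg=me.avg, sem=me.sem,
                min=me_abs.min, min_id=me_abs.min_id,
                max=me_abs.max, max_id=me_abs.max_id,
                n=me.n, n_excluded=me.n_excluded, step_label=label,
                values=me.values, ids=me.ids,
            )
        for rep in (epe, ae, me):
            out.append({
                "step": step, "pct_loss": label, "metric": rep.metric,
                "avg": rep.avg, "sem": rep.sem,
                "min": rep.min, "min_id": rep.min_id,
                "max": rep.max, "max_id": rep.max_id,
                "n": rep.n, "n_excluded": rep.n_excluded,
            })
    return pd.DataFrame(out)
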