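"""Measurement-error assessment across digitization sessions.

Procrustes ANOVA on jointly superimposed replicate digitizations: the
session effect tests for systematic drift between sessions, and the
percentage of measurement error is the within-specimen variance component
expressed as a share of total (between + within) shape variance, overall and
per landmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import LandmarkSample
from .gpa import gpa

__all__ = ["MeasurementErrorResult", "measurement_error_anova"]


@dataclass
class MeasurementErrorResult:
    f_session: float
    df_session: tuple[int, int]
    p_session: float
    pct_me: float
    pct_me_per_landmark: np.ndarray
    var_within: float
    var_between: float


def _shape_dim(k: int, d: int) -> int:
    # dimension of shape space after removing location, scale, rotation
    return k * d - d - d * (d - 1) // 2 - 1


def measurement_error_anova(
    session1: LandmarkSample, session2: LandmarkSample
) -> MeasurementErrorResult:
    """Two-session Procrustes ANOVA.

    Both sessions are superimposed in one joint GPA. The session effect is
    tested against the specimen-by-session interaction with degrees of
    freedom multiplied by the shape-space dimension m (F with (m, (n-1)m)
    df). Percent measurement error comes from the one-way variance
    components: sessions act as replicates of each specimen, sigma^2_within
    = MS_within and sigma^2_between = (MS_among - MS_within)/2, and
    %ME = 100 * sigma^2_w / (sigma^2_b + sigma^2_w).
    """
    from scipy import stats

    if session1.ids != session2.ids:
        raise ValueError("sessions must cover the same specimens in the same order")
    if session1.coords.shape != session2.coords.shape:
        raise ValueError("sessions must share the landmark scheme")

    n, k, d = session1.coords.shape
    coords = np.concatenate([session1.coords, session2.coords], axis=0)
    joint = LandmarkSample(
        coords=coords,
        ids=[f"{i}-s1" for i in session1.ids] + [f"{i}-s2" for i in session2.ids],
        labels=session1.labels,
    )
    res = gpa(joint)
    y = res.aligned.coords.reshape(2 * n, k * d)
    y1, y2 = y[:n], y[n:]

    grand = y.mean(axis=0)
    spec_mean = 0.5 * (y1 + y2)
    sess_mean = np.stack([y1.mean(axis=0), y2.mean(axis=0)])

    per_coord = lambda a: (a**2).reshape(-1, k, d).sum(axis=(0, 2))  # noqa: E731

    ss_spec_lm = 2 * per_coord(spec_mean - grand)
    ss_sess_lm = n * per_coord(sess_mean - grand)
    resid = np.concatenate([y1 - spec_mean, y2 - spec_mean]) - np.concatenate(
        [
            np.tile(sess_mean[0] - grand, (n, 1)),
            np.tile(sess_mean[1] - grand, (n, 1)),
        ]
    )
    ss_int_lm = per_coord(resid)

    m = _shape_dim(k, d)
    ss_sess, ss_int = ss_sess_lm.sum(), ss_int_lm.sum()
    df_sess, df_int = m, (n - 1) * m
    ms_sess = ss_sess / df_sess
    ms_int = ss_int / df_int
    f = ms_sess / ms_int if ms_int > 0 else np.inf
    p = float(stats.f.sf(f, df_sess, df_int)) if np.isfinite(f) else 0.0

    # one-way variance components (sessions as replicates)
    ss_within_lm = per_coord(np.concatenate([y1 - spec_mean, y2 - spec_mean]))
    ss_among_lm = ss_spec_lm
    df_within = n  # n specimens x (2-1) replicates
    df_among = n - 1
    ms_within = ss_within_lm.sum() / (df_within * m)
    ms_among = ss_among_lm.sum() / (df_among * m)
    var_w = ms_within
    var_b = max((ms_among - ms_within) / 2.0, 0.0)
    pct = 100.0 * var_w / (var_b + var_w) if (var_b + var_w) > 0 else 0.0

    # per-landmark: same components from that landmark's coordinate SS
    mw = ss_within_lm / df_within
    ma = ss_among_lm / df_among
    vb = np.maximum((ma - mw) / 2.0, 0.0)
    tot = vb + mw
    pct_lm = np.where(tot > 0, 100.0 * mw / tot, 0.0)

    return MeasurementErrorResult(
        f_session=float(f),
        df_session=(df_sess, df_int),
        p_session=p,
        pct_me=float(pct),
        pct_me_per_landmark=pct_lm,
        var_within=float(var_w),
        var_between=float(var_b),
    )
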