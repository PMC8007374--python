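"""Behavioral scoring: signed residual time and session summaries.

The per-subject performance score is the signed residual time

    SRT = sum_i (2 RACC_i - 1) (MT - T_i)

where RACC_i is the trial's accuracy flag, T_i its reaction latency and MT
the maximum allowed latency: fast correct responses add their unused time,
errors subtract it, so the score balances the speed-accuracy trade-off in a
single number (seconds).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("racc", "t_i", "mt")


def _validate(trials: pd.DataFrame) -> pd.DataFrame:
    if len(trials) == 0:
        raise ValueError("empty trial collection")
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    if not trials["racc"].isin((0, 1)).all():
        raise ValueError("racc must be 0 or 1")
    bad = trials.index[(trials["t_i"] < 0) | (trials["t_i"] > trials["mt"])]
    if len(bad):
        raise ValueError(
            f"latency outside [0, MT] on trial row(s) {list(bad[:5])}"
        )
    return trials


def srt_score(trials: pd.DataFrame) -> float:
    """Signed residual time summed over a trial collection."""
    t = _validate(trials)
    signs = 2 * t["racc"].to_numpy(float) - 1
    return float((signs * (t["mt"].to_numpy(float) - t["t_i"].to_numpy(float))).sum())


def session_summary(
    trials: pd.DataFrame, rt_correct_only: bool = True
) -> pd.DataFrame:
    """Per subject/session summaries: mean RT, accuracy, SRT.

    Mean RT is computed over correct trials by default (``rt_correct_only``);
    it is NaN for a session with no correct trial, in which case accuracy is
    0 and SRT remains defined.
    """
    t = _validate(trials)
    for col in ("subject", "session"):
        if col not in t.columns:
            raise ValueError(f"trial table missing column {col!r}")
    rows = []
    for (subject, session), grp in t.groupby(["subject", "session"], sort=True):
        rt_pool = grp[grp["racc"] == 1] if rt_correct_only else grp
        rows.append(dict(
            subject=subject,
            session=session,
            n_trials=len(grp),
            accuracy=float(grp["racc"].mean()),
            mean_rt=float(rt_pool["t_i"].mean()) if len(rt_pool) else float("nan"),
            srt=srt_score(grp),
        ))
    return pd.DataFrame(rows)


def behavior_session_tests(summary: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of mean RT, accuracy and SRT between the two sessions.

    Expects the output of :func:`session_summary` with exactly two sessions;
    tests session 2 minus session 1 across subjects.
    """
    from scipy import stats

    sessions = sorted(summary["session"].unique())
    if len(sessions) != 2:
        raise ValueError(f"need exactly 2 sessions, got {sessions}")
    wide = summary.pivot(index="subject", columns="session")
    rows = []
    for metric in ("mean_rt", "accuracy", "srt"):
        x1 = wide[(metric, sessions[0])].to_numpy(float)
        x2 = wide[(metric, sessions[1])].to_numpy(float)
        ok = np.isfinite(x1) & np.isfinite(x2)
        if ok.sum() < 3:
            raise ValueError(f"paired test for {metric} needs >= 3 subjects")
        if np.std(x2[ok] - x1[ok]) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(x2[ok], x1[ok])
        rows.append(dict(
            metric=metric, mean_session1=float(x1[ok].mean()),
            mean_session2=float(x2[ok].mean()), t=float(t), p=float(p),
            n_subjects=int(ok.sum()),
        ))
    return pd.DataFrame(rows)
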