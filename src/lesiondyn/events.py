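"""Lesion-level time-to-event derivation.

Target-lesion events come from the fitted growth curves (continuous,
model-derived times); non-target events from recorded RECIST status codes
(first CR/PR = response, first PD = progression); new lesions progress at
their detection time and carry no response record.  Lesions without an
event are censored at the patient's last day in the trial.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .growth import GrowthParams, time_to_progression, time_to_response

logger = logging.getLogger(__name__)

__all__ = [
    "derive_target_events",
    "derive_nontarget_events",
    "derive_newlesion_events",
    "derive_all_events",
]

EVENT_COLUMNS = [
    "patient_id",
    "lesion_id",
    "organ",
    "lesion_class",
    "response_time",
    "response_event",
    "progression_time",
    "progression_event",
]


def _censor(time: float, reached: bool, last_day: float) -> tuple[float, bool]:
    if reached and time <= last_day:
        return float(time), True
    return float(last_day), False


def derive_target_events(
    fits: pd.DataFrame,
    last_day: pd.Series | dict,
    response_fraction: float = 0.20,
    rel: float = 0.30,
    abs_mm3: float = 200.0,
    rule: str = "or",
) -> pd.DataFrame:
    """Model-derived response/progression events for target lesions.

    Parameters
    ----------
    fits : DataFrame
        Empirical-Bayes lesion parameters (columns patient_id, lesion_id,
        organ?, v0, f, kg, kd), as produced by the population fit.
    last_day : mapping patient_id -> last trial day
        Events after this day are censored at it.
    """
    last_day = dict(last_day)
    rows = []
    for r in fits.itertuples():
        if r.patient_id not in last_day:
            raise KeyError(f"no last trial day for patient {r.patient_id!r}")
        ld = float(last_day[r.patient_id])
        p = GrowthParams(v0=r.v0, f=min(max(r.f, 0.0), 1.0), kg=r.kg, kd=r.kd)
        resp = time_to_response(p, response_fraction)
        prog = time_to_progression(p, rel=rel, abs_mm3=abs_mm3, rule=rule)
        rt, re = _censor(resp.time if resp.reached else math.inf, resp.reached, ld)
        pt, pe = _censor(prog.time if prog.reached else math.inf, prog.reached, ld)
        rows.append(
            dict(
                patient_id=r.patient_id,
                lesion_id=r.lesion_id,
                organ=getattr(r, "organ", ""),
                lesion_class="target",
                response_time=rt,
                response_event=re,
                progression_time=pt,
                progression_event=pe,
            )
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def derive_nontarget_events(status_rows: pd.DataFrame) -> pd.DataFrame:
    """Status-code events for non-target lesions.

    Response at the first CR/PR visit, progression at the first PD visit;
    otherwise censored at the lesion's last evaluated visit.  NE visits are
    ignored.
    """
    rows = []
    for (pid, lid), grp in status_rows.sort_values("time").groupby(["patient_id", "lesion_id"]):
        organ = grp["organ"].iloc[0]
        codes = grp["status_code"].fillna("NE")
        times = grp["time"].to_numpy(float)
        last = float(times.max())
        resp_hits = times[codes.isin(["CR", "PR"]).to_numpy()]
        prog_hits = times[(codes == "PD").to_numpy()]
        if not len(codes[codes != "NE"]):
            logger.warning("non-target lesion %s has no evaluable status rows; censored", lid)
        rt, re = (float(resp_hits[0]), True) if len(resp_hits) else (last, False)
        pt, pe = (float(prog_hits[0]), True) if len(prog_hits) else (last, False)
        rows.append(
            dict(
                patient_id=pid,
                lesion_id=lid,
                organ=organ,
                lesion_class="nontarget",
                response_time=rt,
                response_event=re,
                progression_time=pt,
                progression_event=pe,
            )
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def derive_newlesion_events(new_rows: pd.DataFrame, last_day: pd.Series | dict | None = None) -> pd.DataFrame:
    """New lesions progress at their detection time; no response record.

    A detection recorded after the patient's last trial day (data oddity)
    is clamped to the last day with a warning.
    """
    last_day = dict(last_day) if last_day is not None else {}
    rows = []
    for r in new_rows.sort_values("time").drop_duplicates(["patient_id", "lesion_id"]).itertuples():
        t = float(r.time)
        ld = last_day.get(r.patient_id, math.inf)
        if t > ld:
            logger.warning(
                "new lesion %s detected at day %.0f after last trial day %.0f; clamped",
                r.lesion_id, t, ld,
            )
            t = float(ld)
        rows.append(
            dict(
                patient_id=r.patient_id,
                lesion_id=r.lesion_id,
                organ=r.organ,
                lesion_class="new",
                response_time=np.nan,
                response_event=False,
                progression_time=t,
                progression_event=True,
            )
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def derive_all_events(
    fits: pd.DataFrame,
    measurements: pd.DataFrame,
    last_day: pd.Series | dict,
    **target_options,
) -> pd.DataFrame:
    """Full lesion event table: targets (model-derived) + non-targets
    (status codes) + new lesions (detection times).

    The organ column for target fits is taken from the measurement table.
    """
    organs = (
        measurements.drop_duplicates(["patient_id", "lesion_id"])
        .set_index(["patient_id", "lesion_id"])["organ"]
    )
    fits = fits.copy()
    if "organ" not in fits.columns:
        fits["organ"] = [
            organs.get((p, l), "") for p, l in zip(fits["patient_id"], fits["lesion_id"])
        ]
    parts = [derive_target_events(fits, last_day, **target_options)]
    nt = measurements[measurements["lesion_class"] == "nontarget"]
    if len(nt):
        parts.append(derive_nontarget_events(nt))
    new = measurements[measurements["lesion_class"] == "new"]
    if len(new):
        parts.append(derive_newlesion_events(new, last_day))
    out = pd.concat(parts, ignore_index=True)
    return out
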