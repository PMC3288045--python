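"""Plate quality control via the Z'-factor of in-plate controls.

Z' = 1 - 3(sigma_p + sigma_n) / |mu_p - mu_n|, computed from the well-level
POS values of the plate-internal positive and negative control wells with
sample (n-1) standard deviations.  A triplicate plate set is rejected when
any of its plates scores below the acceptance threshold (default 0.2,
boundary accepted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateControlsError, G1ScreenError


@dataclass
class QCReport:
    plate_id: str
    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float
    z_prime: float
    accepted: bool


@dataclass
class PlateSetDecision:
    accepted: bool
    threshold: float
    reports: list[QCReport]
    rejected_plates: list[str]


def z_prime(pos_values: Sequence[float], neg_values: Sequence[float]) -> float:
    """Z'-factor of a plate's control wells.

    Uses the absolute mean difference in the denominator so the statistic
    does not flip sign for assays where the positive control reads low.
    Raises :class:`DegenerateControlsError` when the control means coincide.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise G1ScreenError("need >= 2 control values per group for Z'")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise DegenerateControlsError("control means coincide; Z' undefined")
    sigma_p = pos.std(ddof=1)
    sigma_n = neg.std(ddof=1)
    return 1.0 - 3.0 * (sigma_p + sigma_n) / abs(mu_p - mu_n)


def qc_report(plate_id: str, pos_values: Sequence[float],
              neg_values: Sequence[float], threshold: float = 0.2) -> QCReport:
    zp = z_prime(pos_values, neg_values)
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    return QCReport(
        plate_id=plate_id,
        mu_p=float(pos.mean()), sigma_p=float(pos.std(ddof=1)),
        mu_n=float(neg.mean()), sigma_n=float(neg.std(ddof=1)),
        z_prime=float(zp), accepted=bool(zp >= threshold),
    )


def qc_plate_set(plate_reports: Sequence[QCReport],
                 threshold: float = 0.2) -> PlateSetDecision:
    """Accept or reject a (triplicate) plate set.

    The set is rejected iff any plate's Z' falls strictly below the
    threshold; offending plates are cited in the decision.
    """
    reports = list(plate_reports)
    if not reports:
        raise G1ScreenError("empty plate set")
    rejected = [r.plate_id for r in reports if r.z_prime < threshold]
    return PlateSetDecision(
        accepted=not rejected, threshold=threshold,
        reports=reports, rejected_plates=rejected,
    )


def qc_frame(reports: Sequence[QCReport]) -> pd.DataFrame:
    """Stack QC reports into the QC table dialect."""
    return pd.DataFrame({
        "plate_id": [r.plate_id for r in reports],
        "mu_p": [r.mu_p for r in reports],
        "sigma_p": [r.sigma_p for r in reports],
        "mu_n": [r.mu_n for r in reports],
        "sigma_n": [r.sigma_n for r in reports],
        "z_prime": [r.z_prime for r in reports],
        "accepted": [r.accepted for r in reports],
    })
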