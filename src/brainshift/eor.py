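"""Extent-of-resection classification and modality concordance.

A case is gross total resection (GTR) when the residual tumor volume on the
last intraoperative ultrasound is at most ``gtr_epsilon`` (default 0.0 cm^3,
i.e. an exact zero as recorded in cohort tables); otherwise subtotal
resection (STR).  A case counts as an "extension of resection" when an
intraoperative residual volume (``vol_res_ius_cm3``) is recorded — the
ultrasound finding that triggered further resection.

Exclusions are always data-driven (flags on the record), never hard-coded
case numbers, so the same logic runs on synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .mask_io import CaseRecord

__all__ = ["EORStatus", "EORSummary", "ClassificationError", "classify_case", "cohort_eor"]


class ClassificationError(ValueError):
    """Raised when a case cannot be classified (excluded or missing volume)."""


@dataclass(frozen=True)
class EORStatus:
    case_id: str
    category: str  # "GTR" | "STR"
    extended_resection: bool
    residual_us_cm3: float
    residual_mri_cm3: float | None


@dataclass
class EORSummary:
    """Cohort-level EOR counts and US-vs-MRI concordance."""

    n_analyzed: int = 0
    n_excluded: int = 0
    n_gtr: int = 0
    n_str: int = 0
    n_extended_resection: int = 0
    gtr_epsilon_cm3: float = 0.0
    # concordance over cases with both post-US and post-MRI volumes
    n_with_both_modalities: int = 0
    n_concordant: int = 0
    n_discordant: int = 0
    discordant_case_ids: list = field(default_factory=list)
    statuses: list = field(default_factory=list)

    @property
    def agreement(self) -> float | None:
        """Fraction of two-modality cases where US and MRI agree on residual
        presence; None when no case has both modalities."""
        if self.n_with_both_modalities == 0:
            return None
        return self.n_concordant / self.n_with_both_modalities

    def to_dict(self) -> dict:
        return {
            "n_analyzed": self.n_analyzed,
            "n_excluded": self.n_excluded,
            "n_gtr": self.n_gtr,
            "n_str": self.n_str,
            "n_extended_resection": self.n_extended_resection,
            "gtr_epsilon_cm3": self.gtr_epsilon_cm3,
            "n_with_both_modalities": self.n_with_both_modalities,
            "n_concordant": self.n_concordant,
            "n_discordant": self.n_discordant,
            "discordant_case_ids": list(self.discordant_case_ids),
            "agreement": self.agreement,
            "categories": {s.case_id: s.category for s in self.statuses},
        }


def classify_case(record: CaseRecord, gtr_epsilon: float = 0.0) -> EORStatus:
    """Classify one case as GTR or STR from its post-resectional US volume."""
    if record.exclude_post:
        raise ClassificationError(
            f"case {record.case_id} is excluded from post-resectional analysis"
            + (f" ({record.exclude_post_reason})" if record.exclude_post_reason else "")
        )
    if record.vol_post_us_cm3 is None:
        raise ClassificationError(
            f"case {record.case_id} has no post-resectional US volume"
        )
    category = "GTR" if record.vol_post_us_cm3 <= gtr_epsilon else "STR"
    return EORStatus(
        case_id=record.case_id,
        category=category,
        extended_resection=record.vol_res_ius_cm3 is not None,
        residual_us_cm3=record.vol_post_us_cm3,
        residual_mri_cm3=record.vol_post_mri_cm3,
    )


def cohort_eor(records: Sequence[CaseRecord], gtr_epsilon: float = 0.0) -> EORSummary:
    """EOR counts and US/MRI concordance over the non-excluded cohort."""
    summary = EORSummary(gtr_epsilon_cm3=gtr_epsilon)
    for record in records:
        if record.exclude_post or record.vol_post_us_cm3 is None:
            summary.n_excluded += 1
            continue
        status = classify_case(record, gtr_epsilon)
        summary.statuses.append(status)
        summary.n_analyzed += 1
        if status.category == "GTR":
            summary.n_gtr += 1
        else:
            summary.n_str += 1
        if status.extended_resection:
            summary.n_extended_resection += 1
        if status.residual_mri_cm3 is not None:
            summary.n_with_both_modalities += 1
            us_residual = status.residual_us_cm3 > gtr_epsilon
            mri_residual = status.residual_mri_cm3 > gtr_epsilon
            if us_residual == mri_residual:
                summary.n_concordant += 1
            else:
                summary.n_discordant += 1
                summary.discordant_case_ids.append(status.case_id)
    return summary
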