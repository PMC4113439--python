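"""Tessellated fundus indices and per-eye records.

A tessellated (tigroid) fundus looks redder inside the posterior pole
because thinning of the choroid and RPE pigment exposes the large choroidal
vessels.  Three scalar indices capture this from the mean channel
intensities R, G, B of the analysis disk:

    TFI-1 = (R - G) / R
    TFI-2 = R / (R + G + B)
    TFI-3 = (R - G) / (R + G + B)

All three are ratios of channel means, so they are invariant to a global
brightness rescaling — fundus photographs vary widely in exposure.  By
construction ``TFI-3 = TFI-1 * TFI-2`` exactly.

Eyes are also graded ophthalmoscopically by three independent raters into
non-tessellated (NT), weakly tessellated (WT) and strongly tessellated (ST)
groups; the consensus grade is the one held by at least two raters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .errors import NoConsensusError, TessellaError, UndefinedIndexError
from .image import (
    ChannelStats,
    DEFAULT_ROI_DIAMETER,
    FundusImage,
    Landmarks,
    channel_stats,
    default_roi,
    roi_pixels,
)

__all__ = ["TFISet", "Grade", "EyeRecord", "compute_tfi", "consensus_grade", "eye_record"]


class Grade(enum.IntEnum):
    """Subjective tessellation grade, ordered NT < WT < ST."""

    NT = 0
    WT = 1
    ST = 2

    def __str__(self) -> str:  # CSV serialisation
        return self.name

    @classmethod
    def parse(cls, text: str) -> "Grade":
        try:
            return cls[str(text).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown grade {text!r}; expected NT|WT|ST") from None


@dataclass(frozen=True)
class TFISet:
    """The three tessellation indices for one eye."""

    tfi1: float
    tfi2: float
    tfi3: float


@dataclass(frozen=True)
class EyeRecord:
    """One eye: covariates, rater grades, consensus and indices.

    Covariates: age (years), axial length AL (mm), spherical equivalent SE
    (diopters), subfoveal and nasal choroidal thickness SFCT/NCT (µm).
    """

    eye_id: str
    age: float
    axial_length: float
    spherical_equivalent: float
    sfct: float
    nct: float
    rater_grades: tuple[Grade, Grade, Grade]
    consensus: Grade
    tfi: TFISet

    def __post_init__(self) -> None:
        if self.axial_length <= 0 or self.sfct <= 0 or self.nct <= 0:
            raise ValueError(
                f"eye {self.eye_id}: AL, SFCT, NCT must be positive"
            )
        if sum(g == self.consensus for g in self.rater_grades) < 2:
            raise ValueError(
                f"eye {self.eye_id}: consensus {self.consensus} not held by >=2 raters"
            )


def compute_tfi(stats: ChannelStats) -> TFISet:
    """Compute TFI-1/2/3 from ROI channel means.

    The indices use the disk-wide mean intensities, not per-pixel indices
    averaged afterwards.  Raises :class:`UndefinedIndexError` for a black
    region (R+G+B = 0) or zero mean red (R = 0).
    """
    r, g, b = stats.mean_r, stats.mean_g, stats.mean_b
    total = r + g + b
    if total <= 0:
        raise UndefinedIndexError("black region: R+G+B = 0, all indices undefined")
    if r <= 0:
        raise UndefinedIndexError("zero mean red intensity: TFI-1 undefined")
    return TFISet(tfi1=(r - g) / r, tfi2=r / total, tfi3=(r - g) / total)


def consensus_grade(grades: Sequence[Grade]) -> Grade:
    """Grade held by at least two of the three raters.

    Three mutually distinct grades have no majority; that configuration is
    reported never to occur in practice, but it must fail loudly rather
    than pick arbitrarily.
    """
    if len(grades) != 3:
        raise ValueError(f"expected exactly 3 rater grades, got {len(grades)}")
    for g in grades:
        if grades.count(g) >= 2:
            return g
    raise NoConsensusError(f"no two raters agree: {tuple(str(g) for g in grades)}")


TFI_CSV_COLUMNS = [
    "eye_id", "mean_r", "mean_g", "mean_b", "tfi1", "tfi2", "tfi3", "consensus_grade",
]


def write_tfi_csv(path, rows: Sequence[dict]) -> None:
    """Write the per-eye index table (full precision, one row per eye)."""
    import pandas as pd

    df = pd.DataFrame(list(rows), columns=TFI_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_tfi_csv(path):
    """Read the per-eye index table written by :func:`write_tfi_csv`."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"eye_id": str, "consensus_grade": str})
    if list(df.columns) != TFI_CSV_COLUMNS:
        raise ValueError(
            f"per-eye CSV must have columns {TFI_CSV_COLUMNS}, got {list(df.columns)}"
        )
    return df


def eye_record(
    image: FundusImage,
    landmarks: Landmarks,
    covariates: dict,
    rater_grades: Sequence[Grade],
    diameter: float = DEFAULT_ROI_DIAMETER,
) -> EyeRecord:
    """Assemble one eye's record: ROI placement → channel stats → indices.

    ``covariates`` must provide age, axial_length, spherical_equivalent,
    sfct and nct.  Component failures are re-raised with the eye id
    prepended for traceability.
    """
    eye_id = image.eye_id
    try:
        roi = default_roi(image, landmarks, diameter=diameter)
        stats = channel_stats(roi_pixels(image, roi))
        tfi = compute_tfi(stats)
        consensus = consensus_grade(list(rater_grades))
    except TessellaError as exc:
        raise type(exc)(f"eye {eye_id}: {exc}") from exc
    return EyeRecord(
        eye_id=eye_id,
        age=float(covariates["age"]),
        axial_length=float(covariates["axial_length"]),
        spherical_equivalent=float(covariates["spherical_equivalent"]),
        sfct=float(covariates["sfct"]),
        nct=float(covariates["nct"]),
        rater_grades=tuple(rater_grades),
        consensus=consensus,
        tfi=tfi,
    )
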