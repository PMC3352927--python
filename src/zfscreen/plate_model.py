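"""Shared data model for wells, treatment groups and validation tables.

Both assays (cardiotoxicity video phenotyping and angiogenesis image
quantification) report per-embryo results that are pooled into treatment
groups for statistics, and both were validated against panels of reference
compounds with known human effects.  The panel tables ship with the package
as CSV fixtures and are re-derivable: every printed TP/TN/FN/FP verdict is a
function of the (human effect, observed zebrafish effect) pair.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "CardioCategory",
    "AngioCategory",
    "Verdict",
    "TreatmentGroup",
    "ValidationRecord",
    "MIN_EMBRYOS_PER_GROUP",
    "assign_verdict",
    "load_validation_table",
    "packaged_table",
]

#: Minimum analysable embryos required before group statistics are computed.
MIN_EMBRYOS_PER_GROUP = 10


class CardioCategory(enum.Enum):
    """Four-way automated cardiotoxicity call, plus a no-call flag.

    ``ARRHYTHMIA_21`` is the 2:1 atrio-ventricular block phenotype (atrium
    beating at twice the ventricular rate), the zebrafish signature of ERG
    channel blockade.  ``NO_CALL`` marks embryos whose motion exceeded the
    arrest threshold but produced no significant spectral peak; they are
    excluded from group statistics.
    """

    NO_EFFECT = "No effect"
    BRADYCARDIA = "Bradycardia"
    ARRHYTHMIA_21 = "Arrhythmia 2:1"
    CARDIAC_ARREST = "Cardiac arrest"
    NO_CALL = "No call"


class AngioCategory(enum.Enum):
    """Two-way angiogenesis call at the treatment-group level."""

    INHIBITED = "Inhibited"
    NOT_INHIBITED = "Not inhibited"


class Verdict(enum.Enum):
    TP = "TP"
    TN = "TN"
    FN = "FN"
    FP = "FP"


# Controlled vocabulary of known human effects (cardio panel + angio panel).
HUMAN_EFFECTS = frozenset(
    {
        "Bradycardia",
        "QT-prolong.",
        "Arrhythmia",
        "Cardiac arrest",
        "No effect",
        "Inhibitor",
    }
)

# Controlled vocabulary of observed zebrafish classifications.
OBSERVED_EFFECTS = frozenset(
    {
        "Bradycardia",
        "Arrhythmia 2:1",
        "Arrhythmia",
        "Cardiac arrest",
        "No effect",
        "Inhibited",
    }
)

# Explicit (human effect, observed effect) pairs accepted as true positives.
# The pairing is transcribed from the printed validation verdicts rather
# than derived from a severity rule: the panel accepts cross-severity
# matches (a known bradycardia inducer observed as cardiac arrest counts as
# detected), while a QT-prolongation inducer observed only as bradycardia
# does not (the 2:1 arrhythmia signature was missed).
_TP_PAIRS = frozenset(
    {
        ("Bradycardia", "Bradycardia"),
        ("Bradycardia", "Cardiac arrest"),
        ("QT-prolong.", "Arrhythmia 2:1"),
        ("Arrhythmia", "Arrhythmia"),
        ("Cardiac arrest", "Cardiac arrest"),
        ("Inhibitor", "Inhibited"),
    }
)

# Unicode ratio colon (U+2236) sometimes used in "2:1" labels.
_NORMALISE = str.maketrans({"∶": ":"})


def _norm(label: str) -> str:
    return str(label).strip().translate(_NORMALISE)


def assign_verdict(human_effect: str, observed_effect: str) -> Verdict:
    """Classify one compound's screening outcome as TP/TN/FN/FP.

    A compound with no known effect is a true negative when the assay calls
    no effect and a false positive otherwise.  A compound with a known
    effect is a true positive when the observed category is an accepted
    match for that effect (see ``_TP_PAIRS``) and a false negative when the
    effect was missed or observed as a non-matching category.

    Raises
    ------
    ValueError
        If either label is outside the controlled vocabulary.
    """
    human = _norm(human_effect)
    observed = _norm(observed_effect)
    if human not in HUMAN_EFFECTS:
        raise ValueError(f"unknown human effect label: {human_effect!r}")
    if observed not in OBSERVED_EFFECTS:
        raise ValueError(f"unknown observed effect label: {observed_effect!r}")

    if human == "No effect":
        return Verdict.TN if observed == "No effect" else Verdict.FP
    if (human, observed) in _TP_PAIRS:
        return Verdict.TP
    return Verdict.FN


@dataclass(frozen=True)
class ValidationRecord:
    """One compound row of a validation panel."""

    compound: str
    human_effect: str
    observed_effect: str
    verdict: Verdict
    extra: dict = field(default_factory=dict)


@dataclass
class TreatmentGroup:
    """A compound/concentration condition and its per-embryo results."""

    compound_id: str
    concentration_um: float
    well_ids: list = field(default_factory=list)
    embryo_results: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.concentration_um < 0:
            raise ValueError("concentration must be >= 0 (0 = vehicle control)")

    @property
    def is_control(self) -> bool:
        return self.concentration_um == 0

    @property
    def n_embryos(self) -> int:
        return len(self.embryo_results)

    @property
    def sufficient(self) -> bool:
        """Whether the group meets the minimum size for statistics."""
        return self.n_embryos >= MIN_EMBRYOS_PER_GROUP


_REQUIRED_COLUMNS = ("compound", "human_effect", "observed_effect", "verdict")


def load_validation_table(path: str | Path) -> list[ValidationRecord]:
    """Load a validation panel CSV into one record per compound row.

    The CSV must carry at least the columns ``compound``, ``human_effect``,
    ``observed_effect`` and ``verdict``; any further columns are kept in
    ``ValidationRecord.extra``.  Lines starting with ``#`` are comments.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"validation table {path}: missing column {col!r}")
    extra_cols = [c for c in df.columns if c not in _REQUIRED_COLUMNS]
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = getattr(row, "verdict")
        try:
            verdict = Verdict(_norm(raw))
        except ValueError:
            raise ValueError(
                f"validation table {path}, row {i + 1}: unknown verdict {raw!r}"
            ) from None
        records.append(
            ValidationRecord(
                compound=_norm(row.compound),
                human_effect=_norm(row.human_effect),
                observed_effect=_norm(row.observed_effect),
                verdict=verdict,
                extra={c: df.iloc[i][c] for c in extra_cols},
            )
        )
    return records


def packaged_table(name: str) -> Path:
    """Path to one of the packaged validation fixtures.

    ``name`` is one of ``table2_cardio``, ``table3_cv``, ``table4_angio``.
    """
    ref = resources.files("zfscreen.data").joinpath(f"{name}.csv")
    return Path(str(ref))
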