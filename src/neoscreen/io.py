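"""Reading, validating and quality-gating animal-level trial data.

The unit of observation is one rat pup with a brain-area-loss percentage
(percent tissue loss of the injured hemisphere relative to the contralateral
hemisphere). Records are grouped into experiments, each of which must carry a
saline control arm, and into litters within experiments. An experiment-level
quality gate retains only experiments whose control-group median loss reflects
a moderate injury (median in [35, 50]%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTROL_LABEL = "control"

#: Treatment labels in input files that are normalised to ``control``.
DEFAULT_CONTROL_ALIASES = ("control", "hi/saline", "saline", "hi-saline", "vehicle")

REQUIRED_COLUMNS = (
    "animal_id",
    "experiment_id",
    "litter_id",
    "treatment",
    "sex",
    "area_loss_pct",
)

VALID_SEX = ("male", "female", "unknown")


class ValidationError(ValueError):
    """Raised when records violate the dataset invariants."""


@dataclass(frozen=True)
class HemisphereMeasurement:
    """Ipsilateral/contralateral section areas for one brain section.

    Areas are in arbitrary but consistent units (e.g. ImageJ pixel counts).
    """

    animal_id: str
    section_index: int
    ipsilateral_area: float
    contralateral_area: float

    def __post_init__(self) -> None:
        if self.ipsilateral_area <= 0 or self.contralateral_area <= 0:
            raise ValidationError(
                f"animal {self.animal_id} section {self.section_index}: "
                "hemisphere areas must be strictly positive"
            )
        if self.section_index < 1:
            raise ValidationError("section_index must be >= 1")


def area_loss_percent(measurements: Sequence[HemisphereMeasurement]) -> float:
    """Brain-area-loss percentage from per-section hemisphere areas.

    Section areas are summed across all provided sections before taking the
    ratio, so larger sections carry proportionally more weight::

        loss% = 100 * (1 - sum(ipsilateral) / sum(contralateral))

    clipped below at 0 for the (oedema) case where the ipsilateral sum
    exceeds the contralateral sum.
    """
    if len(measurements) == 0:
        raise ValidationError("at least one hemisphere measurement is required")
    ipsi = sum(m.ipsilateral_area for m in measurements)
    contra = sum(m.contralateral_area for m in measurements)
    return float(max(0.0, 100.0 * (1.0 - ipsi / contra)))


@dataclass
class TrialDataset:
    """Validated animal-level records with provenance notes.

    ``records`` holds one row per animal with columns
    ``animal_id, experiment_id, litter_id, treatment, sex, area_loss_pct``;
    the control arm is labelled ``"control"``.
    """

    records: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_records(self.records)

    @property
    def experiments(self) -> list[str]:
        return sorted(self.records["experiment_id"].unique())

    @property
    def treatments(self) -> list[str]:
        labels = set(self.records["treatment"].unique()) - {CONTROL_LABEL}
        return sorted(labels)

    def experiment(self, experiment_id: str) -> pd.DataFrame:
        sub = self.records[self.records["experiment_id"] == experiment_id]
        if sub.empty:
            raise KeyError(f"unknown experiment {experiment_id!r}")
        return sub

    def control_values_by_litter(
        self, experiment_id: str | None = None, group_by: str = "litter"
    ) -> dict[str, np.ndarray]:
        """Control-arm outcomes keyed by grouping unit.

        ``group_by="litter"`` groups control animals by ``(experiment, litter)``
        (the default for the litter-exclusion procedure); ``"experiment"``
        groups them by experiment.
        """
        ctrl = self.records[self.records["treatment"] == CONTROL_LABEL]
        if experiment_id is not None:
            ctrl = ctrl[ctrl["experiment_id"] == experiment_id]
        if group_by == "litter":
            keys = ctrl["experiment_id"].astype(str) + ":" + ctrl["litter_id"].astype(str)
        elif group_by == "experiment":
            keys = ctrl["experiment_id"].astype(str)
        else:
            raise ValueError("group_by must be 'litter' or 'experiment'")
        return {
            k: grp["area_loss_pct"].to_numpy(float)
            for k, grp in ctrl.groupby(keys.rename("unit"), sort=True)
        }

    def drop_litters(self, litter_keys: Iterable[str]) -> "TrialDataset":
        """Remove every record (all arms) of the given ``exp:litter`` units.

        An experiment whose entire control arm sat in the dropped litters is
        removed as well (it can no longer anchor any comparison); this is
        recorded in provenance.
        """
        keys = set(litter_keys)
        unit = self.records["experiment_id"].astype(str) + ":" + self.records["litter_id"].astype(str)
        kept = self.records[~unit.isin(keys)]
        notes = [f"dropped litters: {sorted(keys)}"]
        has_ctrl = kept.groupby("experiment_id")["treatment"].apply(
            lambda t: (t == CONTROL_LABEL).any()
        )
        orphaned = list(has_ctrl.index[~has_ctrl])
        if orphaned:
            kept = kept[~kept["experiment_id"].isin(orphaned)]
            notes.append(f"removed experiments left without controls: {orphaned}")
        return TrialDataset(kept.reset_index(drop=True), self.provenance + notes)

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.records.copy(), list(self.provenance))


def validate_records(df: pd.DataFrame) -> None:
    """Enforce record-level and dataset-level invariants, with row numbers."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")

    problems: list[str] = []
    loss = pd.to_numeric(df["area_loss_pct"], errors="coerce")
    for row in df.index[loss.isna()]:
        problems.append(f"row {row}: area_loss_pct not a number")
    bad = df.index[(loss < 0) | (loss > 100)]
    for row in bad:
        problems.append(f"row {row}: area_loss_pct={loss[row]} outside [0, 100]")
    for col in ("treatment", "experiment_id"):
        for row in df.index[df[col].astype(str).str.strip() == ""]:
            problems.append(f"row {row}: empty {col}")
    for row in df.index[~df["sex"].isin(VALID_SEX)]:
        problems.append(f"row {row}: sex={df.loc[row, 'sex']!r} not in {VALID_SEX}")

    dup = df.duplicated(subset=["experiment_id", "animal_id"], keep=False)
    if dup.any():
        problems.append(
            f"duplicate (experiment_id, animal_id) pairs at rows {list(df.index[dup])}"
        )
    for exp, grp in df.groupby("experiment_id"):
        if not (grp["treatment"] == CONTROL_LABEL).any():
            problems.append(f"experiment {exp!r} has no control group")

    if problems:
        raise ValidationError("; ".join(problems))


def load_dataset(
    path: str | Path,
    format: str = "csv",
    column_map: Mapping[str, str] | None = None,
    control_aliases: Sequence[str] = DEFAULT_CONTROL_ALIASES,
) -> TrialDataset:
    """Load a trial dataset from a CSV file.

    Parameters
    ----------
    path:
        CSV file with a header row; comma-separated, UTF-8, dot decimals.
    column_map:
        Optional mapping from file column names to the canonical names in
        :data:`REQUIRED_COLUMNS`.
    control_aliases:
        Treatment labels (case-insensitive) normalised to ``"control"``.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns: {missing}")
    aliases = {a.lower() for a in control_aliases}
    df["treatment"] = df["treatment"].astype(str).str.strip()
    is_ctrl = df["treatment"].str.lower().isin(aliases)
    df.loc[is_ctrl, "treatment"] = CONTROL_LABEL
    df["sex"] = df["sex"].astype(str).str.strip().str.lower()
    df["area_loss_pct"] = pd.to_numeric(df["area_loss_pct"], errors="coerce")
    return TrialDataset(df.reset_index(drop=True), [f"loaded from {path}"])


@dataclass(frozen=True)
class QcVerdict:
    experiment_id: str
    control_median: float
    control_n: int
    verdict: str  # retained | excluded_low | excluded_high


@dataclass
class QcReport:
    """Per-experiment moderate-injury quality-gate verdicts."""

    verdicts: list[QcVerdict]

    @property
    def n_excluded(self) -> int:
        return sum(v.verdict != "retained" for v in self.verdicts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(v) for v in self.verdicts])


def qc_filter(
    dataset: TrialDataset, low: float = 35.0, high: float = 50.0
) -> tuple[TrialDataset, QcReport]:
    """Apply the moderate-injury experiment gate.

    Experiments whose control-group median area loss lies in the closed
    interval ``[low, high]`` percent are retained; all others are removed
    entirely (every arm). The defaults encode the moderate-injury window
    35–50%.
    """
    verdicts: list[QcVerdict] = []
    keep: list[str] = []
    for exp in dataset.experiments:
        ctrl = dataset.experiment(exp)
        ctrl = ctrl[ctrl["treatment"] == CONTROL_LABEL]["area_loss_pct"]
        med = float(ctrl.median())
        if med < low:
            verdict = "excluded_low"
        elif med > high:
            verdict = "excluded_high"
        else:
            verdict = "retained"
            keep.append(exp)
        verdicts.append(QcVerdict(exp, med, int(ctrl.size), verdict))
    kept = dataset.records[dataset.records["experiment_id"].isin(keep)]
    out = TrialDataset(
        kept.reset_index(drop=True),
        dataset.provenance + [f"qc gate [{low}, {high}]%: kept {len(keep)} experiments"],
    )
    return out, QcReport(verdicts)
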