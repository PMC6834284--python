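"""Clinical and abundance input handling.

Readers for the three tab-delimited inputs of the survival screen — a
clinical table with per-patient survival annotation, a nonnegative TPM
abundance matrix (features x patients), and a transcript-to-gene map —
plus transcript-to-gene aggregation and the expression-eligibility filter
applied before threshold scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalCohort",
    "AbundanceMatrix",
    "FeatureMap",
    "DEFAULT_EXCLUSION_TERMS",
    "read_clinical",
    "read_abundance",
    "read_feature_map",
    "aggregate_to_genes",
    "filter_eligible",
]

#: Clinical annotation phrases treated as confounding by default. These are
#: configuration, not a fixed rule: other clinical dialects can supply their
#: own phrases (or none).
DEFAULT_EXCLUSION_TERMS = ("Prior malignancy", "Synchronous malignancy")

_MISSING_TOKENS = {"", "na", "nan", "none", "null", "--", "[not available]",
                   "[not applicable]", "not reported"}


@dataclass
class ClinicalCohort:
    """Per-patient right-censored survival data.

    ``time`` is the observed duration in days: days to death for patients
    whose death was recorded (``event == 1``), days to last follow-up for
    censored patients (``event == 0``).
    """

    patient_ids: np.ndarray
    time: np.ndarray
    event: np.ndarray
    report: Mapping[str, int] | None = field(default=None, compare=False, repr=False)
    #: free-form generator metadata (latent censoring times etc.); never
    #: consulted by the statistics, only by the synthetic-data module.
    extras: dict | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=np.int8)
        if not (self.patient_ids.size == self.time.size == self.event.size):
            raise ValueError("patient_ids, time and event must have equal length")
        if self.patient_ids.size != len(set(self.patient_ids)):
            raise ValueError("duplicate patient identifiers in cohort")
        if not np.all(np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValueError("survival times must be finite and nonnegative")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")

    @property
    def n(self) -> int:
        return int(self.patient_ids.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, keep: Sequence) -> "ClinicalCohort":
        """Return a sub-cohort.

        ``keep`` is either a boolean mask aligned to the cohort or an
        iterable of patient ids (order preserved as given).
        """
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {p: i for i, p in enumerate(self.patient_ids)}
            try:
                idx = np.array([pos[p] for p in keep], dtype=int)
            except KeyError as exc:  # pragma: no cover - message path
                raise KeyError(f"patient {exc.args[0]!r} not in cohort") from None
        extras = None
        if self.extras is not None:
            extras = {
                k: (np.asarray(v)[idx] if isinstance(v, np.ndarray) else v)
                for k, v in self.extras.items()
            }
        return ClinicalCohort(self.patient_ids[idx], self.time[idx],
                              self.event[idx], extras=extras)

    def reorder(self, patient_ids: Sequence) -> "ClinicalCohort":
        """Return the cohort with patients in the given order (must be a
        permutation of the cohort's patient set)."""
        if set(patient_ids) != set(self.patient_ids):
            raise ValueError("patient set mismatch when reordering cohort")
        return self.subset(list(patient_ids))


@dataclass
class AbundanceMatrix:
    """Nonnegative TPM values, features (rows) x patients (columns)."""

    data: pd.DataFrame
    report: Mapping[str, object] | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate patient id {dup!r}")
        values = df.to_numpy(dtype=float, copy=False)
        if np.isnan(values).any():
            i, j = map(int, next(zip(*np.nonzero(np.isnan(values)))))
            raise ValueError(
                f"missing/non-numeric value at feature {df.index[i]!r}, "
                f"patient {df.columns[j]!r}")
        if (values < 0).any():
            i, j = map(int, next(zip(*np.nonzero(values < 0))))
            raise ValueError(
                f"negative abundance at feature {df.index[i]!r}, "
                f"patient {df.columns[j]!r}")

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def patient_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def align_to(self, cohort: ClinicalCohort) -> "AbundanceMatrix":
        """Reorder columns to the cohort's patient order (sets must match)."""
        if set(self.data.columns) != set(cohort.patient_ids):
            raise ValueError("abundance patients do not match cohort patients")
        return AbundanceMatrix(self.data.loc[:, list(cohort.patient_ids)])


@dataclass
class FeatureMap:
    """Transcript -> (gene, biotype) map; each transcript maps to one gene."""

    data: pd.DataFrame  # columns: transcript_id, gene_id, biotype

    def __post_init__(self) -> None:
        required = {"transcript_id", "gene_id", "biotype"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"feature map missing columns: {sorted(missing)}")
        dup = self.data["transcript_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"transcript mapped more than once: "
                f"{self.data['transcript_id'][dup].iloc[0]!r}")

    @property
    def gene_of(self) -> Mapping[str, str]:
        return dict(zip(self.data["transcript_id"], self.data["gene_id"]))

    def is_protein_coding(self, transcript_id: str) -> bool:
        row = self.data.loc[self.data["transcript_id"] == transcript_id]
        if row.empty:
            raise KeyError(transcript_id)
        return row["biotype"].iloc[0] == "protein_coding"


def _parse_days(raw, column: str, row_label) -> float | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if text.lower() in _MISSING_TOKENS:
        return None
    try:
        value = float(text)
    except ValueError:
        raise ValueError(
            f"non-numeric {column} value {text!r} for patient {row_label!r}")
    if value < 0:
        raise ValueError(f"negative {column} ({value}) for patient {row_label!r}")
    return value


def read_clinical(path, exclusion_terms: Iterable[str] = DEFAULT_EXCLUSION_TERMS,
                  ) -> ClinicalCohort:
    """Load a clinical survival table.

    Expected columns: ``patient_id``, ``days_to_death``,
    ``days_to_last_followup``; any further columns are treated as free
    annotation text. A patient is removed when any annotation cell contains
    one of ``exclusion_terms`` (case-insensitive substring), or when both
    survival columns are missing. Removal counts are recorded in
    ``cohort.report``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("patient_id", "days_to_death", "days_to_last_followup")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate patient id {dup!r} in clinical table")

    terms = [t.lower() for t in exclusion_terms]
    annotation_cols = [c for c in df.columns if c not in required]

    ids, times, events = [], [], []
    n_excluded = n_missing = 0
    for _, row in df.iterrows():
        pid = row["patient_id"]
        if terms and annotation_cols:
            blob = " ".join(str(row[c]) for c in annotation_cols).lower()
            if any(t in blob for t in terms):
                n_excluded += 1
                continue
        death = _parse_days(row["days_to_death"], "days_to_death", pid)
        follow = _parse_days(row["days_to_last_followup"],
                             "days_to_last_followup", pid)
        if death is None and follow is None:
            n_missing += 1
            continue
        if death is not None:
            ids.append(pid); times.append(death); events.append(1)
        else:
            ids.append(pid); times.append(follow); events.append(0)

    cohort = ClinicalCohort(np.array(ids, dtype=object),
                            np.array(times), np.array(events))
    cohort.report = {
        "n_rows": int(len(df)),
        "excluded_by_annotation": n_excluded,
        "missing_survival": n_missing,
        "retained": cohort.n,
    }
    return cohort


def read_abundance(path) -> AbundanceMatrix:
    """Load a feature x patient TPM table (first column = feature ids)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    converted = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = converted.isna().to_numpy()
    if bad.any():
        i, j = map(int, next(zip(*np.nonzero(bad))))
        raise ValueError(
            f"non-numeric abundance value {raw.iat[i, j]!r} at feature "
            f"{raw.index[i]!r}, patient {raw.columns[j]!r}")
    return AbundanceMatrix(converted)


def read_feature_map(path) -> FeatureMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return FeatureMap(df)


def aggregate_to_genes(matrix: AbundanceMatrix, feature_map: FeatureMap,
                       on_unmapped: str = "error") -> AbundanceMatrix:
    """Sum transcript abundances within each gene, per patient.

    ``on_unmapped``: "error" raises listing unmapped transcript ids;
    "skip" drops them and counts them in the result's report.
    """
    gene_of = feature_map.gene_of
    index = matrix.data.index
    unmapped = [t for t in index if t not in gene_of]
    if unmapped and on_unmapped == "error":
        shown = ", ".join(map(repr, unmapped[:10]))
        more = "" if len(unmapped) <= 10 else f" (+{len(unmapped) - 10} more)"
        raise ValueError(f"unmapped transcripts: {shown}{more}")
    if on_unmapped not in ("error", "skip"):
        raise ValueError(f"unknown on_unmapped mode {on_unmapped!r}")

    kept = matrix.data.drop(index=unmapped)
    genes = kept.index.map(gene_of)
    summed = kept.groupby(genes, sort=True).sum()
    summed.index.name = matrix.data.index.name
    out = AbundanceMatrix(summed)
    out.report = {"n_transcripts": int(len(index)),
                  "n_unmapped_skipped": len(unmapped),
                  "n_genes": int(len(summed))}
    return out


def filter_eligible(matrix: AbundanceMatrix, l: float = 0.15,
                    ) -> tuple[AbundanceMatrix, dict]:
    """Keep features expressed (TPM > 0) in at least a fraction ``1 - l``
    of patients.

    ``l`` is the lower percentile bound of the threshold scan: features
    whose zero fraction exceeds ``l`` cannot support every split in the
    scan range and are excluded from the screen. Constant-valued features
    are dropped separately — every split of a constant feature produces
    identical groups, so no informative minimum exists.
    """
    if not 0 < l < 0.5:
        raise ValueError("l must lie in (0, 0.5)")
    values = matrix.data.to_numpy(dtype=float)
    frac_expressed = (values > 0).mean(axis=1)
    constant = (values == values[:, :1]).all(axis=1)
    low = (frac_expressed < 1 - l) & ~constant
    keep = ~low & ~constant
    out = AbundanceMatrix(matrix.data.loc[keep])
    report = {
        "n_input": int(len(matrix.data)),
        "dropped_low_expression": [f for f, m in zip(matrix.data.index, low) if m],
        "dropped_constant": [f for f, m in zip(matrix.data.index, constant) if m],
        "n_kept": int(keep.sum()),
    }
    return out, report
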