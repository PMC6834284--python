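"""Mutational-signature validation of survival-split patient groups.

Consensus SNV calls (intersection over variant callers) are binned into
the 96 COSMIC substitution-in-trinucleotide-context classes, decomposed as
nonnegative linear combinations of reference signatures, and compared
between low- and high-expression patient groups with Mood's median test.
Smoking-style confounder checks and an exact binomial enrichment test
complete the stage.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import (binom, chi2_contingency, fisher_exact, mannwhitneyu,
                         ttest_ind)

__all__ = [
    "SUBSTITUTIONS", "BASES", "mutation_types", "classify_snv",
    "read_maf", "intersect_callers", "build_profiles", "read_signatures",
    "validate_signatures", "fit_contributions", "fit_all",
    "MoodsResult", "moods_median_test", "compare_groups", "confounder_tests",
    "signature_enrichment_test",
]

BASES = "ACGT"
PYRIMIDINES = {"C", "T"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
#: the six pyrimidine-reference substitution classes, COSMIC order
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mutation_types() -> list[str]:
    """The 96 class labels, substitution-major then 5'-flank then 3'-flank
    (e.g. ``A[C>A]A, A[C>A]C, ...``)."""
    return [f"{five}[{sub}]{three}"
            for sub in SUBSTITUTIONS
            for five, three in itertools.product(BASES, BASES)]


_TYPE_INDEX = {label: i for i, label in enumerate(mutation_types())}


def classify_snv(ref: str, alt: str, context: str) -> str | None:
    """Map one SNV to its 96-class label.

    Purine-reference mutations are reverse-complemented to the pyrimidine
    convention first. Returns None for non-ACGT context bases. Raises for
    a context whose length is not 3 or whose middle base disagrees with
    the reference allele.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3:
        raise ValueError(f"context {context!r} must have length 3")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    if any(b not in BASES for b in context) or alt not in BASES:
        return None
    if context[1] != ref:
        raise ValueError(
            f"context middle base {context[1]!r} != ref allele {ref!r}")
    if ref not in PYRIMIDINES:
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
        context = _revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


_MAF_ALIASES = {
    "patient_id": ("patient_id", "Tumor_Sample_Barcode"),
    "chrom": ("chrom", "Chromosome"),
    "pos": ("pos", "Start_Position"),
    "ref": ("ref", "Reference_Allele"),
    "alt": ("alt", "Tumor_Seq_Allele2"),
    "caller": ("caller", "Caller", "Center"),
    "context": ("context", "CONTEXT", "ref_context"),
}


def read_maf(path) -> pd.DataFrame:
    """Load somatic variant calls from a MAF-style TSV.

    Standard MAF column names and plain lower-case names are both accepted
    (1-based coordinates). Only single-base substitutions are retained for
    profiling. Returns a catalog frame with columns patient_id, caller,
    chrom, pos, ref, alt and (if available) context.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                     keep_default_na=False)
    resolved = {}
    for canon, aliases in _MAF_ALIASES.items():
        col = next((a for a in aliases if a in df.columns), None)
        if col is not None:
            resolved[canon] = col
    required = {"patient_id", "chrom", "pos", "ref", "alt"}
    if missing := required - set(resolved):
        raise ValueError(f"MAF missing columns: {sorted(missing)}")
    out = pd.DataFrame({canon: df[col] for canon, col in resolved.items()})
    if "caller" not in out.columns:
        out["caller"] = "unknown"
    out["pos"] = out["pos"].astype(int)
    snv = (out["ref"].str.len() == 1) & (out["alt"].str.len() == 1) \
        & out["ref"].str.upper().isin(list(BASES)) \
        & out["alt"].str.upper().isin(list(BASES)) \
        & (out["ref"] != out["alt"])
    return out[snv].reset_index(drop=True)


_SITE_KEYS = ["patient_id", "chrom", "pos", "ref", "alt"]


def intersect_callers(catalog: pd.DataFrame,
                      required_callers: Iterable[str]) -> pd.DataFrame:
    """Consensus records: keep a (patient, site, substitution) record iff
    every required caller reports it. The output is untagged (no caller
    column)."""
    required = set(required_callers)
    if not required:
        raise ValueError("required_callers must be nonempty")
    present = set(catalog["caller"].unique())
    if missing := required - present:
        raise ValueError(f"required caller(s) absent from catalog: "
                         f"{sorted(missing)}")
    sub = catalog[catalog["caller"].isin(required)]
    grouped = sub.drop_duplicates(_SITE_KEYS + ["caller"]) \
                 .groupby(_SITE_KEYS, sort=False)["caller"].nunique()
    keep = grouped[grouped == len(required)].index
    extra = [c for c in ("context",) if c in catalog.columns]
    consensus = sub.drop_duplicates(_SITE_KEYS)[_SITE_KEYS + extra]
    mask = pd.MultiIndex.from_frame(consensus[_SITE_KEYS]).isin(keep)
    return consensus[mask].reset_index(drop=True)


def build_profiles(consensus: pd.DataFrame, context_source=None,
                   patients: Sequence[str] | None = None,
                   ) -> tuple[pd.DataFrame, dict]:
    """Bin consensus SNVs into per-patient 96-class count profiles.

    Context comes from the catalog's ``context`` column unless
    ``context_source`` (a ``callable(chrom, pos) -> str`` returning the
    1-based pos-1..pos+1 trinucleotide, e.g. a wrapped reference FASTA) is
    given. Records with non-ACGT context are skipped and counted.
    ``patients`` optionally fixes the row set/order (patients with no
    consensus SNVs get all-zero profiles).
    """
    labels = mutation_types()
    if patients is None:
        patients = list(dict.fromkeys(consensus["patient_id"]))
    counts = pd.DataFrame(0, index=list(patients), columns=labels, dtype=int)
    n_skipped = 0
    for row in consensus.itertuples():
        if context_source is not None:
            context = context_source(row.chrom, int(row.pos))
        else:
            context = getattr(row, "context", None)
            if context is None:
                raise ValueError("catalog has no context column and no "
                                 "context_source was supplied")
        label = classify_snv(row.ref, row.alt, str(context))
        if label is None:
            n_skipped += 1
            continue
        counts.at[row.patient_id, label] += 1
    return counts, {"n_records": int(len(consensus)),
                    "n_skipped_context": n_skipped}


def validate_signatures(signatures: pd.DataFrame) -> pd.DataFrame:
    """Check a 96 x K signature matrix (rows = the 96 classes in COSMIC
    order, columns = signatures, each column summing to 1)."""
    if list(signatures.index) != mutation_types():
        if set(signatures.index) == set(mutation_types()):
            signatures = signatures.loc[mutation_types()]
        else:
            raise ValueError("signature matrix rows must be the 96 classes")
    values = signatures.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("signature entries must be nonnegative")
    sums = values.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("signature columns must sum to 1")
    return signatures


def read_signatures(path) -> pd.DataFrame:
    """Load a signature definition TSV (first column = the 96 class
    labels, remaining columns = signatures)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_signatures(df)


def fit_contributions(profile, signatures: pd.DataFrame) -> np.ndarray:
    """Nonnegative least-squares refit of one 96-bin profile:
    ``min ||S w - profile||_2  s.t.  w >= 0``."""
    signatures = validate_signatures(signatures)
    y = np.asarray(profile, dtype=float).ravel()
    if y.size != 96:
        raise ValueError("profile must have 96 bins")
    w, _ = nnls(signatures.to_numpy(dtype=float), y)
    return w


def fit_all(profiles: pd.DataFrame, signatures: pd.DataFrame) -> pd.DataFrame:
    """Per-patient signature contributions (patients x signatures)."""
    signatures = validate_signatures(signatures)
    rows = {pid: fit_contributions(profiles.loc[pid, mutation_types()],
                                   signatures)
            for pid in profiles.index}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(signatures.columns))


@dataclass(frozen=True)
class MoodsResult:
    statistic: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    method: str           # "chi2", "exact", or "degenerate"
    degenerate: bool = False


def moods_median_test(a, b) -> MoodsResult:
    """Mood's median test for two samples.

    Counts values strictly above vs not-above the pooled median per group
    (values equal to the median count as not-above) and applies the 2x2
    chi-square test without continuity correction, falling back to
    Fisher's exact (hypergeometric) test when any expected cell is below
    5. All values are retained, including zeros.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        table = ((0, a.size), (0, b.size))
        return MoodsResult(0.0, 1.0, table, "degenerate", True)
    med = float(np.median(pooled))
    table = ((int((a > med).sum()), int((a <= med).sum())),
             (int((b > med).sum()), int((b <= med).sum())))
    arr = np.array(table, dtype=float)
    col_tot = arr.sum(axis=0)
    if (col_tot == 0).any():
        return MoodsResult(0.0, 1.0, table, "degenerate", True)
    expected = np.outer(arr.sum(axis=1), col_tot) / arr.sum()
    if (expected < 5).any():
        _, p = fisher_exact(table, alternative="two-sided")
        return MoodsResult(float("nan"), float(p), table, "exact")
    stat, p, _, _ = chi2_contingency(arr, correction=False)
    return MoodsResult(float(stat), float(p), table, "chi2")


def compare_groups(contributions: pd.DataFrame, labels: Mapping[str, str],
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-signature group comparison of contribution weights.

    ``labels`` maps patient_id -> "low" / "high" (e.g. from the optimal
    split of a survival-significant feature). Each signature gets Mood's
    median-test p-value and the difference of means (high minus low);
    rows with p < alpha are flagged significant.
    """
    lab = pd.Series({p: labels[p] for p in contributions.index})
    low = contributions.loc[lab == "low"]
    high = contributions.loc[lab == "high"]
    if low.empty or high.empty:
        raise ValueError("both groups must be nonempty")
    rows = []
    for sig in contributions.columns:
        res = moods_median_test(low[sig], high[sig])
        diff = float(high[sig].mean() - low[sig].mean())
        rows.append((sig, res.p_value, diff, res.p_value < alpha, res.method))
    return pd.DataFrame(rows, columns=["signature", "p_value",
                                       "mean_high_minus_low", "significant",
                                       "method"])


def _two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sample test for equal proportions (2x2 chi-square with
    continuity correction, as in R's prop.test)."""
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table.sum(axis=0).min() == 0:
        return 1.0
    _, p, _, _ = chi2_contingency(table, correction=True)
    return float(p)


def confounder_tests(covariates: pd.DataFrame, labels: Mapping[str, str],
                     kinds: Mapping[str, str]) -> pd.DataFrame:
    """Dispatch per-variable group-difference tests by declared kind.

    * ``metric``: Welch two-sample t-test;
    * ``integer``: Wilcoxon rank-sum (normal approximation, tie-corrected);
    * ``binary``: two-sample test for equal proportions.

    Missing values are dropped per variable and counted; a variable with
    no usable values in either group is skipped with a warning (p = NaN).
    """
    lab = pd.Series({p: labels[p] for p in covariates.index})
    rows = []
    for var, kind in kinds.items():
        if kind not in ("metric", "integer", "binary"):
            raise ValueError(f"unknown variable kind {kind!r} for {var!r}")
        col = pd.to_numeric(covariates[var], errors="coerce")
        ok = col.notna()
        lo = col[ok & (lab == "low")]
        hi = col[ok & (lab == "high")]
        n_missing = int((~ok).sum())
        if lo.empty or hi.empty:
            warnings.warn(f"variable {var!r} has no usable values in a group; skipped")
            rows.append((var, kind, float("nan"), 0, n_missing))
            continue
        if kind == "metric":
            p = float(ttest_ind(lo, hi, equal_var=False).pvalue)
        elif kind == "integer":
            p = float(mannwhitneyu(lo, hi, alternative="two-sided",
                                   method="asymptotic").pvalue)
        else:
            p = _two_proportion_test(int((lo != 0).sum()), lo.size,
                                     int((hi != 0).sum()), hi.size)
        rows.append((var, kind, p, int(lo.size + hi.size), n_missing))
    return pd.DataFrame(rows, columns=["variable", "kind", "p_value",
                                       "n_used", "n_missing"])


def signature_enrichment_test(n_significant: int, n_total: int,
                              background_p: float) -> float:
    """One-sided exact binomial enrichment: P(X >= n_significant) for
    X ~ Binomial(n_total, background_p)."""
    if not 0 <= n_significant <= n_total:
        raise ValueError("need 0 <= n_significant <= n_total")
    if not 0 < background_p < 1:
        raise ValueError("background_p must lie in (0, 1)")
    return float(binom.sf(n_significant - 1, n_total, background_p))
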