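"""Synthetic data with the statistical structure the pipeline assumes.

Every generator is a pure function of its parameters and a seed, returns a
ground-truth object sufficient to score the downstream stage, and can
materialize its output in the same text dialects the readers consume
(clinical TSV, abundance TSV, gene-model TSV, BioGRID-style TAB3, 3did
flat file, HMMER domtblout, MAF). The survival model is exponential with
uniform right-censoring — the simplest generative model satisfying the
proportional-hazards alternative the logrank screen is powered against.
All identifiers and files are synthetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import AbundanceMatrix, ClinicalCohort
from .mgg import DDICatalog, DomainAssignment, GeneModel, Interactome, MGGPath
from .mutsig import mutation_types, validate_signatures

__all__ = [
    "SyntheticTruth", "simulate_cohort", "simulate_expression",
    "simulate_interactome", "simulate_mutations", "synthetic_signatures",
    "write_clinical", "write_abundance", "write_gene_model",
    "write_biogrid_tab3", "write_3did_flat", "write_domtblout", "write_maf",
    "write_signatures", "write_truth_json",
]


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside generated data.

    Only the fields relevant to the generator that produced the object are
    populated; each is sufficient to score its downstream stage without
    re-reading generator internals.
    """

    planted_features: dict = field(default_factory=dict)
    cohort: ClinicalCohort | None = None            # shared-cohort mode
    cohorts: dict | None = None                     # per-feature mode
    significant_variants: set = field(default_factory=set)
    expected_paths: set = field(default_factory=set)
    signature_weights: pd.DataFrame | None = None


def _event_probability(hazard: float, horizon: float) -> float:
    """P(death observed) for exponential(hazard) survival vs uniform
    (0, horizon] censoring: 1 - (1 - exp(-hazard*horizon))/(hazard*horizon)."""
    x = hazard * horizon
    return 1.0 - (1.0 - np.exp(-x)) / x


def simulate_cohort(n: int, event_rate_target: float = 0.35,
                    baseline_hazard: float = 1e-3,
                    censor_horizon: float | None = None,
                    seed: int = 0) -> ClinicalCohort:
    """Exponential survival with uniform right-censoring.

    The default hazard of 1e-3 per day (mean latent survival ~1000 days)
    and an event fraction near 0.35 mirror the shape of a mid-sized tumor
    cohort with a few years of follow-up. When ``censor_horizon`` is not
    given it is solved so the expected event fraction equals
    ``event_rate_target``; ``censor_horizon=inf`` observes every death.
    The latent censoring times and hazard are kept in ``cohort.extras`` so
    expression generators can re-draw survival under planted hazards.
    """
    if n < 2:
        raise ValueError("need at least two patients")
    rng = np.random.default_rng(seed)
    if censor_horizon is None:
        if not 0 < event_rate_target < 1:
            raise ValueError("event_rate_target must lie in (0, 1)")
        censor_horizon = float(brentq(
            lambda c: _event_probability(baseline_hazard, c) - event_rate_target,
            1e-6 / baseline_hazard, 1e6 / baseline_hazard))
    latent = rng.exponential(1.0 / baseline_hazard, size=n)
    if np.isinf(censor_horizon):
        censor = np.full(n, np.inf)
    else:
        censor = rng.uniform(0.0, censor_horizon, size=n)
    event = (latent <= censor).astype(int)
    time = np.minimum(latent, censor)
    ids = np.array([f"P{i + 1:05d}" for i in range(n)], dtype=object)
    cohort = ClinicalCohort(ids, time, event)
    cohort.extras = {"censor_times": censor,
                     "baseline_hazard": baseline_hazard,
                     "censor_horizon": censor_horizon}
    return cohort


def _replant_survival(cohort: ClinicalCohort, high_mask: np.ndarray,
                      hazard_ratio: float, rng) -> ClinicalCohort:
    """Redraw survival for designated high-expression patients with the
    baseline hazard multiplied by ``hazard_ratio``; censoring times are
    reused unchanged."""
    if cohort.extras is None or "censor_times" not in cohort.extras:
        raise ValueError("cohort lacks latent censoring information; use a "
                         "cohort from simulate_cohort")
    hazard = cohort.extras["baseline_hazard"] * hazard_ratio
    censor = np.asarray(cohort.extras["censor_times"], dtype=float)
    time = cohort.time.copy()
    event = cohort.event.astype(int).copy()
    n_high = int(high_mask.sum())
    latent = rng.exponential(1.0 / hazard, size=n_high)
    time[high_mask] = np.minimum(latent, censor[high_mask])
    event[high_mask] = (latent <= censor[high_mask]).astype(int)
    out = ClinicalCohort(cohort.patient_ids.copy(), time, event)
    out.extras = dict(cohort.extras)
    return out


def simulate_expression(cohort: ClinicalCohort, n_null: int,
                        planted: Sequence[tuple[float, float]] = (),
                        seed: int = 0, mode: str = "shared",
                        log_mean: float = 1.0, log_sigma: float = 1.0,
                        ) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Expression features with and without a planted survival effect.

    Null features are log-normal TPM draws independent of survival.
    Each planted feature ``(hazard_ratio, split_fraction)`` designates a
    random fraction ``split_fraction`` of patients as "high"; their
    survival is redrawn with the hazard multiplied by ``hazard_ratio``,
    and the feature's abundance assigns the largest log-normal draws to
    the designated set so the rank split recovers the designation.

    ``mode="shared"``: one designation drives one shared cohort (all
    planted features must agree on it; the perturbed cohort is
    ``truth.cohort``). ``mode="per-feature"``: each planted feature
    perturbs a private cohort copy (``truth.cohorts[feature_id]``); null
    features are screened against the unperturbed cohort.
    """
    rng = np.random.default_rng(seed)
    s = cohort.n
    truth = SyntheticTruth()
    rows, ids = [], []

    def _planted_row(high_mask: np.ndarray) -> np.ndarray:
        draws = np.sort(rng.lognormal(log_mean, log_sigma, size=s))
        n_high = int(high_mask.sum())
        x = np.empty(s)
        lo_vals = draws[:s - n_high]
        hi_vals = draws[s - n_high:]
        x[~high_mask] = rng.permutation(lo_vals)
        x[high_mask] = rng.permutation(hi_vals)
        return x

    if mode == "shared":
        if len({(hr, f) for hr, f in planted}) > 1:
            raise ValueError("shared-cohort mode requires a single "
                             "(hazard_ratio, split_fraction) designation")
        shared = cohort
        high_mask = None
        if planted:
            hr, frac = planted[0]
            n_high = int(round(frac * s))
            high_idx = rng.choice(s, size=n_high, replace=False)
            high_mask = np.zeros(s, dtype=bool)
            high_mask[high_idx] = True
            shared = _replant_survival(cohort, high_mask, hr, rng)
        truth.cohort = shared
        for i, (hr, frac) in enumerate(planted):
            fid = f"PLANT{i + 1:03d}"
            ids.append(fid)
            rows.append(_planted_row(high_mask))
            truth.planted_features[fid] = {
                "hazard_ratio": hr, "split_fraction": frac,
                "high_patients": sorted(cohort.patient_ids[high_mask])}
    elif mode == "per-feature":
        truth.cohorts = {}
        for i, (hr, frac) in enumerate(planted):
            fid = f"PLANT{i + 1:03d}"
            n_high = int(round(frac * s))
            high_idx = rng.choice(s, size=n_high, replace=False)
            high_mask = np.zeros(s, dtype=bool)
            high_mask[high_idx] = True
            truth.cohorts[fid] = _replant_survival(cohort, high_mask, hr, rng)
            ids.append(fid)
            rows.append(_planted_row(high_mask))
            truth.planted_features[fid] = {
                "hazard_ratio": hr, "split_fraction": frac,
                "high_patients": sorted(cohort.patient_ids[high_mask])}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for i in range(n_null):
        ids.append(f"NULL{i + 1:04d}")
        rows.append(rng.lognormal(log_mean, log_sigma, size=s))

    data = pd.DataFrame(np.array(rows).reshape(len(ids), s), index=ids,
                        columns=list(cohort.patient_ids))
    return AbundanceMatrix(data), truth


def simulate_interactome(n_genes: int = 20, isoforms_per_gene: int = 3,
                         domain_vocab_size: int = 30,
                         n_planted_paths: int = 5, seed: int = 0,
                         n_background_edges: int | None = None,
                         n_background_ddis: int = 10,
                         ) -> tuple[GeneModel, DomainAssignment, Interactome,
                                    DDICatalog, SyntheticTruth]:
    """A toy PPI/DDI universe with planted gained/ghost rewiring paths.

    Background per-isoform domain sets are drawn from a vocabulary that
    never appears in the DDI catalog, and background DDIs use a disjoint
    decoy vocabulary never assigned to isoforms; each planted path uses a
    fresh reserved accession pair. The expected path set recorded in the
    truth object is therefore exactly the output of the graph-construction
    cascade — no accidental paths can arise.
    """
    if isoforms_per_gene < 2:
        raise ValueError("isoforms_per_gene must be >= 2")
    if n_genes < 2 * n_planted_paths or n_genes < 2:
        raise ValueError("need at least max(2, 2*n_planted_paths) genes")
    rng = np.random.default_rng(seed)

    gene_ids = [f"GENE{i + 1:03d}" for i in range(n_genes)]
    genes = {g: [(f"{g}-T{j + 1}", True) for j in range(isoforms_per_gene)]
             for g in gene_ids}
    assignable = [f"PF1{i:04d}" for i in range(domain_vocab_size)]
    decoys = [f"PF2{i:04d}" for i in range(max(1, n_background_ddis * 2))]

    domains: dict[str, set] = {}
    for g in gene_ids:
        for tx, _ in genes[g]:
            k = int(rng.integers(0, 4))
            domains[tx] = set(rng.choice(assignable, size=k, replace=False))

    edges = set()
    if n_background_edges is None:
        n_background_edges = n_genes
    while len(edges) < n_background_edges:
        a, b = rng.choice(n_genes, size=2, replace=False)
        edges.add(tuple(sorted((gene_ids[a], gene_ids[b]))))

    ddi_pairs = []
    for i in range(n_background_ddis):
        ddi_pairs.append((decoys[2 * i], decoys[2 * i + 1]))

    truth = SyntheticTruth()
    order = rng.permutation(n_genes)
    sig_genes = [gene_ids[i] for i in order[:n_planted_paths]]
    partner_genes = [gene_ids[i] for i in order[n_planted_paths:2 * n_planted_paths]]
    for i in range(n_planted_paths):
        g, pg = sig_genes[i], partner_genes[i]
        sig_tx = genes[g][0][0]
        partner_tx = genes[pg][0][0]
        status = "gained" if i % 2 == 0 else "ghost"
        da, db = f"PF3{2 * i:04d}", f"PF3{2 * i + 1:04d}"
        domains[partner_tx].add(db)
        if status == "gained":
            domains[sig_tx].add(da)
        else:
            for tx, _ in genes[g][1:]:
                domains[tx].add(da)
        edges.add(tuple(sorted((g, pg))))
        ddi_pairs.append((da, db))
        truth.significant_variants.add(sig_tx)
        truth.expected_paths.add(
            MGGPath(sig_tx, da, status, db, partner_tx, pg))

    gene_model = GeneModel(genes)
    assignment = DomainAssignment({tx: frozenset(v) for tx, v in domains.items()})
    interactome = Interactome(frozenset(edges),
                              report={"n_edges": len(edges)})
    return gene_model, assignment, interactome, DDICatalog(ddi_pairs), truth


def synthetic_signatures(n_signatures: int = 5, seed: int = 0,
                         block_mass: float = 0.9) -> pd.DataFrame:
    """Well-separated synthetic reference signatures (96 x K).

    Each signature places ``block_mass`` of its probability on a private
    block of the 96 classes (Dirichlet-distributed within the block) and
    spreads the rest over the remaining classes. These are synthetic
    stand-ins shaped like a COSMIC-style signature table, not estimates of
    real mutational processes; users may drop in a real 96 x K TSV.
    """
    if not 1 <= n_signatures <= 32:
        raise ValueError("n_signatures must lie in 1..32")
    rng = np.random.default_rng(seed)
    labels = mutation_types()
    block = 96 // n_signatures
    cols = {}
    for k in range(n_signatures):
        w = np.zeros(96)
        lo, hi = k * block, (k + 1) * block if k < n_signatures - 1 else 96
        w[lo:hi] = block_mass * rng.dirichlet(np.ones(hi - lo))
        rest = np.setdiff1d(np.arange(96), np.arange(lo, hi))
        w[rest] = (1 - block_mass) * rng.dirichlet(np.ones(rest.size))
        cols[f"S{k + 1}"] = w / w.sum()
    return validate_signatures(pd.DataFrame(cols, index=labels))


_DEFAULT_CALLERS = ("muse", "mutect", "somaticsniper", "varscan")


def simulate_mutations(n_patients: int, signatures: pd.DataFrame,
                       weights, n_mutations: int = 5000,
                       caller_dropout: float = 0.05, seed: int = 0,
                       callers: Sequence[str] = _DEFAULT_CALLERS,
                       ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-patient SNV catalogs drawn from known signature mixtures.

    ``weights`` is an (n_patients x K) array of mixture weights (rows sum
    to 1). Each patient receives ``n_mutations`` multinomial draws from
    the mixed 96-class profile, materialized as SNV records with
    consistent trinucleotide contexts (about half are emitted on the
    purine strand to exercise reverse-complement handling). Each caller
    copy independently drops records with probability ``caller_dropout``.
    """
    signatures = validate_signatures(signatures)
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if weights.shape != (n_patients, signatures.shape[1]):
        raise ValueError("weights must be n_patients x n_signatures")
    if not np.allclose(weights.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("weight rows must sum to 1")
    if not 0 <= caller_dropout < 1:
        raise ValueError("caller_dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    labels = mutation_types()
    sig_matrix = signatures.to_numpy(dtype=float)

    records = []
    patient_ids = [f"P{i + 1:05d}" for i in range(n_patients)]
    for i, pid in enumerate(patient_ids):
        profile = sig_matrix @ weights[i]
        profile = profile / profile.sum()
        counts = rng.multinomial(n_mutations, profile)
        pos = 1000
        for label, c in zip(labels, counts):
            five, sub, three = label[0], label[2:5], label[6]
            ref, alt = sub[0], sub[2]
            context = five + ref + three
            for _ in range(int(c)):
                pos += int(rng.integers(10, 1000))
                chrom = f"chr{int(rng.integers(1, 23))}"
                r, a, ctx = ref, alt, context
                if rng.random() < 0.5:  # purine-strand representation
                    comp = str.maketrans("ACGT", "TGCA")
                    r, a = r.translate(comp), a.translate(comp)
                    ctx = ctx.translate(comp)[::-1]
                records.append((pid, chrom, pos, r, a, ctx))

    rows = []
    for rec in records:
        for caller in callers:
            if rng.random() >= caller_dropout:
                rows.append((rec[0], caller) + rec[1:])
    catalog = pd.DataFrame(rows, columns=["patient_id", "caller", "chrom",
                                          "pos", "ref", "alt", "context"])
    truth = SyntheticTruth(signature_weights=pd.DataFrame(
        weights, index=patient_ids, columns=list(signatures.columns)))
    return catalog, truth


# ---------------------------------------------------------------------------
# writers for the text dialects the readers consume

def write_clinical(cohort: ClinicalCohort, path,
                   annotations: dict | None = None) -> None:
    """Write the clinical TSV dialect (days_to_death filled for events,
    days_to_last_followup for censored patients)."""
    ann_cols = sorted(annotations) if annotations else []
    with open(path, "w") as fh:
        fh.write("\t".join(["patient_id", "days_to_death",
                            "days_to_last_followup"] + ann_cols) + "\n")
        for pid, t, e in zip(cohort.patient_ids, cohort.time, cohort.event):
            death = f"{t:g}" if e == 1 else ""
            follow = f"{t:g}" if e == 0 else ""
            extra = [str(annotations[c].get(pid, "")) for c in ann_cols] \
                if annotations else []
            fh.write("\t".join([pid, death, follow] + extra) + "\n")


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    out = matrix.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def write_gene_model(gene_model: GeneModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tis_protein_coding\n")
        for gene in sorted(gene_model.genes):
            for tx, pc in gene_model.genes[gene]:
                fh.write(f"{gene}\t{tx}\t{int(pc)}\n")


def write_biogrid_tab3(interactome: Interactome, path,
                       taxon: str = "9606") -> None:
    """Write edges in a minimal BioGRID TAB3-style dialect."""
    cols = ["#BioGRID Interaction ID", "Official Symbol Interactor A",
            "Official Symbol Interactor B", "Experimental System Type",
            "Organism ID Interactor A", "Organism ID Interactor B"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, (a, b) in enumerate(sorted(interactome.edges)):
            fh.write(f"{i + 1}\t{a}\t{b}\tphysical\t{taxon}\t{taxon}\n")


def write_3did_flat(ddi: DDICatalog, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(ddi.pairs):
            fh.write(f"#=ID\t{a}_fam\t{b}_fam\t({a}.1@Pfam\t{b}.1@Pfam)\n")


def write_domtblout(domains: DomainAssignment, path,
                    e_value: float = 1e-30) -> None:
    """Write domain assignments as hmmscan-style per-domain rows
    (synthetic domtblout: only the columns the reader consumes carry
    meaningful values)."""
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name  "
                 "accession   qlen   E-value  score  bias   #  of  "
                 "c-Evalue  i-Evalue  score  bias  from    to  from    "
                 "to  from    to  acc description of target\n")
        for tx in sorted(domains.domains):
            for acc in sorted(domains.domains[tx]):
                fields = [f"{acc}_dom", f"{acc}.1", "200", tx, "-", "500",
                          f"{e_value:g}", "100.0", "0.1", "1", "1",
                          f"{e_value:g}", f"{e_value:g}", "99.0", "0.1",
                          "1", "200", "10", "210", "10", "210", "0.98", "-"]
                fh.write(" ".join(fields) + "\n")


def write_maf(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def write_signatures(signatures: pd.DataFrame, path) -> None:
    out = validate_signatures(signatures).copy()
    out.index.name = "mutation_type"
    out.to_csv(path, sep="\t")


def write_truth_json(truth: SyntheticTruth, path) -> None:
    payload = {
        "planted_features": truth.planted_features,
        "significant_variants": sorted(truth.significant_variants),
        "expected_paths": [
            {"sig_variant": p.sig_variant, "sig_domain": p.sig_domain,
             "sig_domain_status": p.sig_domain_status,
             "partner_domain": p.partner_domain,
             "partner_variant": p.partner_variant,
             "partner_gene": p.partner_gene}
            for p in sorted(truth.expected_paths)],
    }
    if truth.signature_weights is not None:
        payload["signature_weights"] = {
            pid: dict(row) for pid, row in
            truth.signature_weights.round(10).iterrows()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
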