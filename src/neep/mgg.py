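"""Multi-granularity graphs: isoform-level interaction rewiring.

Protein-protein interactions are reported at the gene level, but protein
domains — the structural units that mediate many interactions — differ
between isoforms of the same gene. This module expands a gene-level
interactome to variant-variant pairs and emits
variant-domain-domain-variant paths in which a survival-significant,
protein-coding isoform carries a *gained* domain (present in it, absent
from every insignificant sibling isoform) or misses a *ghost* domain
(present in at least one insignificant sibling, absent from it), and that
domain has structurally supported interaction (a DDI catalog entry) with a
domain present on an isoform of the interacting gene. Ghost domains
predict lost interactions, gained domains predict gained interactions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Interactome", "GeneModel", "DomainAssignment", "DDICatalog", "MGGPath",
    "read_biogrid", "read_3did", "read_domains", "read_gene_model",
    "classify_domains", "build_mgg", "write_mgg", "read_mgg",
    "MGG_COLUMNS", "significant_features",
]

HUMAN_TAXON = "9606"


@dataclass
class Interactome:
    """Deduplicated set of unordered gene-gene interaction pairs."""

    edges: frozenset
    report: Mapping[str, int] | None = field(default=None, compare=False, repr=False)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


@dataclass
class GeneModel:
    """gene_id -> list of (transcript_id, is_protein_coding)."""

    genes: Mapping[str, list[tuple[str, bool]]]

    def __post_init__(self) -> None:
        seen = set()
        for gene, isoforms in self.genes.items():
            for tx, _ in isoforms:
                if tx in seen:
                    raise ValueError(f"transcript {tx!r} listed under multiple genes")
                seen.add(tx)

    def transcripts(self, gene_id: str) -> list[str]:
        return [tx for tx, _ in self.genes[gene_id]]

    def is_protein_coding(self, transcript_id: str) -> bool:
        for isoforms in self.genes.values():
            for tx, pc in isoforms:
                if tx == transcript_id:
                    return pc
        raise KeyError(transcript_id)

    @property
    def gene_of(self) -> dict[str, str]:
        return {tx: g for g, iso in self.genes.items() for tx, _ in iso}

    @classmethod
    def from_feature_map(cls, feature_map) -> "GeneModel":
        genes: dict[str, list[tuple[str, bool]]] = {}
        for _, row in feature_map.data.iterrows():
            genes.setdefault(row["gene_id"], []).append(
                (row["transcript_id"], row["biotype"] == "protein_coding"))
        return cls(genes)


@dataclass
class DomainAssignment:
    """transcript_id -> set of Pfam accessions (version suffix stripped)."""

    domains: Mapping[str, frozenset]
    report: Mapping[str, int] | None = field(default=None, compare=False, repr=False)

    def get(self, transcript_id: str) -> frozenset:
        return self.domains.get(transcript_id, frozenset())

    def __getitem__(self, transcript_id: str) -> frozenset:
        return self.get(transcript_id)


class DDICatalog:
    """Symmetric catalog of domain-domain interaction pairs."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs = frozenset(tuple(sorted(p)) for p in pairs)

    def __contains__(self, pair) -> bool:
        a, b = pair
        return tuple(sorted((a, b))) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def partners_of(self, domain: str) -> set[str]:
        out = set()
        for a, b in self.pairs:
            if a == domain:
                out.add(b)
            if b == domain:
                out.add(a)
        return out


@dataclass(frozen=True, order=True)
class MGGPath:
    """One variant-domain-domain-variant path.

    ``sig_domain_status`` is "gained" or "ghost"; the interpretation is the
    corresponding predicted rewiring ("gained-interaction" for a gained
    domain, "lost-interaction" for a ghost domain, which the significant
    isoform lacks)."""

    sig_variant: str
    sig_domain: str
    sig_domain_status: str
    partner_domain: str
    partner_variant: str
    partner_gene: str

    @property
    def interpretation(self) -> str:
        return ("gained-interaction" if self.sig_domain_status == "gained"
                else "lost-interaction")


MGG_COLUMNS = ["sig_variant", "sig_domain", "sig_domain_status",
               "partner_domain", "partner_variant", "partner_gene",
               "interpretation"]

_ACCESSION_VERSION = re.compile(r"\.\d+$")


def _strip_version(accession: str) -> str:
    return _ACCESSION_VERSION.sub("", accession)


def _find_column(columns, *candidates):
    lowered = {c.lower().lstrip("#"): c for c in columns}
    for cand in candidates:
        if cand.lower() in lowered:
            return lowered[cand.lower()]
    return None


def read_biogrid(path, taxon: str = HUMAN_TAXON,
                 id_kind: str = "symbol") -> Interactome:
    """Load a BioGRID tab-delimited file (TAB2 or TAB3, auto-detected).

    Keeps rows whose experimental system type is "physical" and whose two
    interactors both belong to ``taxon`` (human by default), then
    deduplicates unordered gene pairs. ``id_kind`` selects the identifier
    namespace: "symbol" (official symbols) or "entrez".
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.lstrip("#") for c in df.columns]

    sys_col = _find_column(df.columns, "Experimental System Type")
    # TAB3 uses "Organism ID Interactor A"; TAB2 "Organism Interactor A"
    org_a = _find_column(df.columns, "Organism ID Interactor A",
                         "Organism Interactor A")
    org_b = _find_column(df.columns, "Organism ID Interactor B",
                         "Organism Interactor B")
    if id_kind == "symbol":
        id_a = _find_column(df.columns, "Official Symbol Interactor A")
        id_b = _find_column(df.columns, "Official Symbol Interactor B")
    elif id_kind == "entrez":
        id_a = _find_column(df.columns, "Entrez Gene Interactor A")
        id_b = _find_column(df.columns, "Entrez Gene Interactor B")
    else:
        raise ValueError(f"unknown id_kind {id_kind!r}")
    missing = [name for name, col in (
        ("Experimental System Type", sys_col),
        ("Organism [ID] Interactor A", org_a),
        ("Organism [ID] Interactor B", org_b),
        ("interactor identifier A", id_a), ("interactor identifier B", id_b),
    ) if col is None]
    if missing:
        raise ValueError(
            "not a BioGRID TAB2/TAB3 file; missing columns: " + ", ".join(missing))

    n_total = len(df)
    physical = df[sys_col].str.lower() == "physical"
    df = df[physical]
    n_physical = len(df)
    human = (df[org_a] == str(taxon)) & (df[org_b] == str(taxon))
    df = df[human]
    n_human = len(df)

    edges = set()
    for a, b in zip(df[id_a], df[id_b]):
        if a and b:
            edges.add(tuple(sorted((a, b))))
    return Interactome(frozenset(edges), report={
        "n_rows": n_total, "n_physical": n_physical,
        "n_taxon_filtered": n_human, "n_edges": len(edges)})


def read_3did(path) -> DDICatalog:
    """Load a DDI catalog from a 3did flat file (``#=ID`` lines carry the
    Pfam pair) or a two-column TSV fallback."""
    pairs = []
    with open(path) as fh:
        lines = fh.readlines()
    flat = any(line.startswith("#=ID") for line in lines)
    if flat:
        paren = re.compile(r"\(([^)]*)\)")
        for line in lines:
            if not line.startswith("#=ID"):
                continue
            m = paren.search(line)
            if not m:
                continue
            accs = [_strip_version(tok.split("@")[0])
                    for tok in m.group(1).split()]
            if len(accs) >= 2:
                pairs.append((accs[0], accs[1]))
    else:
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) >= 2:
                pairs.append((_strip_version(fields[0]),
                              _strip_version(fields[1])))
    if not pairs:
        raise ValueError("no parsable domain-domain pairs found")
    return DDICatalog(pairs)


def _looks_like_accession(token: str) -> bool:
    return bool(re.match(r"^PF\d+", token))


def read_domains(path, e_value_cutoff: float = 0.01) -> DomainAssignment:
    """Load per-isoform domain hits.

    Accepts HMMER3 per-domain tabular output (domtblout; rows kept when the
    independent per-domain E-value is <= ``e_value_cutoff``) or a plain TSV
    of (transcript_id, accession[, e_value]). Accession version suffixes
    (".N") are stripped. Malformed domtblout rows are skipped with a
    warning and counted in the report.
    """
    domains: dict[str, set] = {}
    n_rows = n_kept = n_malformed = n_above_cutoff = 0
    with open(path) as fh:
        data_lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    is_domtbl = bool(data_lines) and len(data_lines[0].split()) >= 14

    for line in data_lines:
        n_rows += 1
        if is_domtbl:
            fields = line.split()
            if len(fields) < 14:
                n_malformed += 1
                continue
            try:
                ievalue = float(fields[12])
            except ValueError:
                n_malformed += 1
                continue
            # hmmscan: target (cols 0-1) is the domain profile; hmmsearch:
            # query (cols 3-4) is. Prefer whichever side carries a Pfam
            # accession.
            if _looks_like_accession(fields[1]):
                acc, tx = fields[1], fields[3]
            elif _looks_like_accession(fields[4]):
                acc, tx = fields[4], fields[0]
            elif _looks_like_accession(fields[0]):
                acc, tx = fields[0], fields[3]
            else:
                n_malformed += 1
                continue
            if ievalue > e_value_cutoff:
                n_above_cutoff += 1
                continue
        else:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                n_malformed += 1
                continue
            tx, acc = fields[0], fields[1]
            if len(fields) >= 3:
                try:
                    if float(fields[2]) > e_value_cutoff:
                        n_above_cutoff += 1
                        continue
                except ValueError:
                    n_malformed += 1
                    continue
        domains.setdefault(tx, set()).add(_strip_version(acc))
        n_kept += 1

    if n_malformed:
        warnings.warn(f"skipped {n_malformed} malformed domain rows")
    return DomainAssignment(
        {tx: frozenset(accs) for tx, accs in domains.items()},
        report={"n_rows": n_rows, "n_kept": n_kept,
                "n_malformed": n_malformed, "n_above_cutoff": n_above_cutoff})


def read_gene_model(path) -> GeneModel:
    """Load a gene model TSV: gene_id, transcript_id, is_protein_coding."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "transcript_id", "is_protein_coding"}
    if missing := required - set(df.columns):
        raise ValueError(f"gene model missing columns: {sorted(missing)}")
    genes: dict[str, list[tuple[str, bool]]] = {}
    truthy = {"1", "true", "yes", "protein_coding"}
    for _, row in df.iterrows():
        genes.setdefault(row["gene_id"], []).append(
            (row["transcript_id"],
             str(row["is_protein_coding"]).strip().lower() in truthy))
    return GeneModel(genes)


def classify_domains(isoforms: Iterable[str], domains: DomainAssignment,
                     sig_variant: str,
                     significant: Iterable[str] = ()) -> tuple[frozenset, frozenset]:
    """Gained and ghost domains of a significant isoform within its gene.

    Let U be the union of domains over the gene's survival-insignificant
    isoforms (siblings of ``sig_variant`` that are not themselves in
    ``significant``). Then::

        gained = domains(sig_variant) - U    (predicted gained interactions)
        ghost  = U - domains(sig_variant)    (predicted lost interactions)

    Requires the gene to have at least two isoforms.
    """
    isoforms = list(isoforms)
    if sig_variant not in isoforms:
        raise ValueError(f"{sig_variant!r} is not an isoform of this gene")
    if len(isoforms) < 2:
        raise ValueError("gene lacks multiple isoforms")
    significant = set(significant) | {sig_variant}
    insignificant = [tx for tx in isoforms if tx not in significant]
    union = frozenset().union(*(domains.get(tx) for tx in insignificant)) \
        if insignificant else frozenset()
    own = domains.get(sig_variant)
    return own - union, union - own


def significant_features(results) -> set[str]:
    """Extract the significant feature-id set from screen results (a frame
    with feature_id/significant columns) or any iterable of ids."""
    if isinstance(results, pd.DataFrame):
        return set(results.loc[results["significant"], "feature_id"])
    return set(results)


def build_mgg(results, gene_model: GeneModel, interactome: Interactome,
              domains: DomainAssignment, ddi: DDICatalog,
              ) -> tuple[list[MGGPath], dict[str, int]]:
    """Run the path-construction filter cascade.

    Stages (counts of surviving ordered variant pairs are logged):

    1. expand every gene-gene interaction to all ordered variant pairs;
    2. keep pairs whose left variant is survival-significant and
       protein-coding;
    3. keep pairs supported by a DDI between a domain of the left variant
       (present, gained or ghost) and a domain present on the right variant;
    4. keep only paths through a gained or ghost left domain;
    5. drop left genes lacking multiple isoforms.

    Returns the de-duplicated path list (sorted) and the per-stage counts.
    """
    sig = significant_features(results)
    gene_of = gene_model.gene_of
    counts: dict[str, int] = {}

    if len(interactome) == 0:
        warnings.warn("empty interactome; no paths can be built")

    # stage 1: ordered variant pairs over gene-gene edges
    ordered_gene_pairs = []
    for a, b in interactome:
        ordered_gene_pairs.append((a, b))
        if a != b:
            ordered_gene_pairs.append((b, a))
    n_stage1 = 0
    for ga, gb in ordered_gene_pairs:
        if ga in gene_model.genes and gb in gene_model.genes:
            n_stage1 += len(gene_model.genes[ga]) * len(gene_model.genes[gb])
    counts["variant_pairs"] = n_stage1

    # stage 2: left variant significant and protein-coding
    candidates = []  # (left_tx, left_gene, right_gene)
    n_stage2 = 0
    for ga, gb in ordered_gene_pairs:
        if ga not in gene_model.genes or gb not in gene_model.genes:
            continue
        right_txs = gene_model.transcripts(gb)
        for tx, pc in gene_model.genes[ga]:
            if tx in sig and pc:
                n_stage2 += len(right_txs)
                candidates.append((tx, ga, gb))
    counts["left_significant_coding"] = n_stage2

    # domain classification per (gene, significant isoform)
    class_cache: dict[str, tuple[frozenset, frozenset]] = {}
    for tx, ga, _ in candidates:
        if tx not in class_cache:
            isoforms = gene_model.transcripts(ga)
            if len(isoforms) >= 2:
                class_cache[tx] = classify_domains(isoforms, domains, tx, sig)
            else:
                class_cache[tx] = (frozenset(), frozenset())

    # stages 3-5
    n_stage3 = n_stage4 = n_stage5 = 0
    paths = set()
    for tx, ga, gb in candidates:
        gained, ghost = class_cache[tx]
        left_any = domains.get(tx) | ghost            # present u gained u ghost
        left_special = gained | ghost
        multi = len(gene_model.transcripts(ga)) >= 2
        for right_tx, _ in gene_model.genes[gb]:
            right_doms = domains.get(right_tx)
            supported = [(da, db) for da in left_any for db in right_doms
                         if (da, db) in ddi]
            if not supported:
                continue
            n_stage3 += 1
            special = [(da, db) for da, db in supported if da in left_special]
            if not special:
                continue
            n_stage4 += 1
            if not multi:
                continue
            n_stage5 += 1
            for da, db in special:
                status = "gained" if da in gained else "ghost"
                paths.add(MGGPath(tx, da, status, db, right_tx, gb))
    counts["ddi_supported_pairs"] = n_stage3
    counts["gained_or_ghost_pairs"] = n_stage4
    counts["multi_isoform_pairs"] = n_stage5
    counts["paths"] = len(paths)
    return sorted(paths), counts


def write_mgg(paths: Iterable[MGGPath], out, graphml=None) -> None:
    """Write paths as a TSV (sorted, de-duplicated); optionally export the
    quadripartite graph as GraphML."""
    unique = sorted(set(paths))
    with open(out, "w") as fh:
        fh.write("\t".join(MGG_COLUMNS) + "\n")
        for p in unique:
            fh.write("\t".join([p.sig_variant, p.sig_domain,
                                p.sig_domain_status, p.partner_domain,
                                p.partner_variant, p.partner_gene,
                                p.interpretation]) + "\n")
    if graphml is not None:
        import networkx as nx
        g = nx.Graph()
        for p in unique:
            v, d1 = f"variant:{p.sig_variant}", f"domain:{p.sig_domain}"
            d2, w = f"domain:{p.partner_domain}", f"variant:{p.partner_variant}"
            g.add_node(v, layer="sig_variant")
            g.add_node(d1, layer="sig_domain", status=p.sig_domain_status)
            g.add_node(d2, layer="partner_domain")
            g.add_node(w, layer="partner_variant", gene=p.partner_gene)
            g.add_edge(v, d1)
            g.add_edge(d1, d2, kind="ddi")
            g.add_edge(d2, w)
        nx.write_graphml(g, graphml)


def read_mgg(path) -> list[MGGPath]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return sorted({MGGPath(r.sig_variant, r.sig_domain, r.sig_domain_status,
                           r.partner_domain, r.partner_variant, r.partner_gene)
                   for r in df.itertuples()})
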