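"""Evidence-based review of annotation suggestions and functional summaries.

Integrates per-protein peptide coverage, applied sequence corrections and
external improvement suggestions to confirm or reject pseudogene calls and
gene joins; detects contiguous same-category gene clusters (e.g. ABC-type
carbohydrate-uptake transporter operons); and summarizes pathway
completeness from product annotations and peptide support.

Decision rules (total over suggestion kinds):

* pseudogene flag, 0% peptide coverage  -> ``pseudogene_confirmed``
* pseudogene flag, coverage > 0%        -> ``pseudogene_rejected``
* join, member coverage > 0% and reading frame restored by an applied
  correction                            -> ``join_applied``
* join otherwise                        -> ``join_rejected``
* anything else                         -> ``no_change``

"Frame restored" means the joined interval, after correction and liftover,
translates stop-free from the upstream gene's start to the downstream
gene's stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .proteogenomic_db import translate_frame
from .records import (
    CorrectionRecord,
    GeneFeature,
    GenomeRecord,
    SuggestionRecord,
    TransporterGene,
    ValidationError,
    reverse_complement,
)
from .coverage_maps import format_percent

DECISIONS = (
    "pseudogene_confirmed",
    "pseudogene_rejected",
    "join_applied",
    "join_rejected",
    "no_change",
)


@dataclass
class ReviewDecision:
    locus_tags: tuple[str, ...]
    input_flag: str
    peptide_coverage: tuple[float, ...]
    frame_intact_after_correction: bool
    decision: str
    rationale: str


# ---------------------------------------------------------------------------
# pseudogene / join review


def _coverage_lookup(coverage_table) -> Mapping[str, float]:
    if isinstance(coverage_table, Mapping):
        return coverage_table
    df = coverage_table
    return dict(zip(df["locus_tag"], df["percent"].astype(float)))


def review_pseudogenes(
    suggestions: Sequence[SuggestionRecord],
    coverage_table,
    corrections: Sequence[CorrectionRecord],
    genome: GenomeRecord,
    corrected_genome: Optional[GenomeRecord] = None,
) -> list[ReviewDecision]:
    """Apply the decision rules to every suggestion.

    ``coverage_table`` maps locus tags to peptide coverage percent (a dict or
    the frame from ``protein_peptide_coverage``).  ``genome`` supplies the
    pre-correction annotation; ``corrected_genome`` (with lifted features),
    when given, is used for the stop-free translation check of joins —
    otherwise the presence of an applied correction within the joined span
    stands in for the frame check.
    """
    cov = _coverage_lookup(coverage_table)
    known = {f.locus_tag for f in genome.features}
    decisions: list[ReviewDecision] = []
    for s in suggestions:
        missing = [t for t in s.locus_tags if t not in known]
        if missing:
            raise ValidationError(f"suggestion references unknown locus {missing[0]}")
        pcts = tuple(float(cov.get(t, 0.0)) for t in s.locus_tags)
        if s.suggestion == "pseudogene":
            if max(pcts) > 0:
                decision, why = "pseudogene_rejected", (
                    f"peptide coverage {pcts[0]:.0f}% contradicts the pseudogene call"
                )
            else:
                decision, why = "pseudogene_confirmed", "no peptides associated with locus"
            frame_ok = False
        elif s.suggestion == "join":
            frame_ok = _join_frame_restored(s.locus_tags, corrections, genome, corrected_genome)
            if max(pcts) > 0 and frame_ok:
                decision, why = "join_applied", (
                    "member peptide coverage and an applied correction restoring the frame"
                )
            else:
                decision, why = "join_rejected", (
                    "no peptide coverage" if max(pcts) == 0 else "reading frame not restored"
                )
        else:
            frame_ok = False
            decision, why = "no_change", f"suggestion kind {s.suggestion} reviewed, no action"
        decisions.append(
            ReviewDecision(
                locus_tags=s.locus_tags,
                input_flag=s.suggestion,
                peptide_coverage=pcts,
                frame_intact_after_correction=frame_ok,
                decision=decision,
                rationale=why,
            )
        )
    return decisions


def _join_frame_restored(
    locus_tags: tuple[str, ...],
    corrections: Sequence[CorrectionRecord],
    genome: GenomeRecord,
    corrected_genome: Optional[GenomeRecord],
) -> bool:
    feats = [genome.feature(t) for t in locus_tags]
    span_start = min(f.start for f in feats)
    span_end = max(f.end for f in feats)
    has_edit = any(
        c.applied and span_start <= c.position <= span_end for c in corrections
    )
    if not has_edit:
        return False
    if corrected_genome is None:
        return True
    strand = feats[0].strand
    cfeats = [corrected_genome.feature(t) for t in locus_tags]
    lo = min(f.start for f in cfeats)
    hi = max(f.end for f in cfeats)
    nt = corrected_genome.subsequence(lo, hi)
    if strand == "-":
        nt = reverse_complement(nt)
    aa = translate_frame(nt, 1)
    internal = aa[:-1] if aa.endswith("*") else aa
    return "*" not in internal and "X" not in internal


# ---------------------------------------------------------------------------
# cluster detection and summaries


@dataclass
class GeneCluster:
    category: str
    strand: str
    locus_tags: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.locus_tags)


def detect_clusters(
    genome: GenomeRecord,
    category_labels: Mapping[str, str],
    max_gap_genes: int = 0,
) -> list[GeneCluster]:
    """Group category-labelled loci into maximal same-strand contiguous runs.

    ``category_labels`` maps locus tags to a functional category (loci absent
    from it are uncategorised).  A run may skip up to ``max_gap_genes``
    uncategorised loci; singletons count as clusters.
    """
    clusters: list[GeneCluster] = []
    current: Optional[GeneCluster] = None
    gap = 0
    for f in genome.features:
        cat = category_labels.get(f.locus_tag)
        if cat is None:
            gap += 1
            if current is not None and gap > max_gap_genes:
                clusters.append(current)
                current = None
            continue
        if current is not None and (cat != current.category or f.strand != current.strand):
            clusters.append(current)
            current = None
        if current is None:
            current = GeneCluster(category=cat, strand=f.strand)
        current.locus_tags.append(f.locus_tag)
        gap = 0
    if current is not None:
        clusters.append(current)
    return clusters


def summarize_clusters(transporter_genes: Sequence[TransporterGene]) -> dict:
    """Counts over a transporter table: clusters, genes, subunit tallies,
    peptide-covered genes (> 0%), and clusters with every member covered."""
    by_cluster: dict[str, list[TransporterGene]] = {}
    for g in transporter_genes:
        by_cluster.setdefault(g.cluster_id, []).append(g)
    img_tally = {"S": 0, "M": 0, "N": 0}
    abcdb_tally = {"S": 0, "M": 0, "N": 0, "X": 0}
    for g in transporter_genes:
        img_tally[g.img_subunit] += 1
        abcdb_tally[g.abcdb_subunit] += 1
    covered = [g for g in transporter_genes if g.coverage_percent > 0]
    fully = [
        cid
        for cid, members in by_cluster.items()
        if all(m.coverage_percent > 0 for m in members)
    ]
    cut2 = [g for g in transporter_genes if g.family == "CUT2"]
    n_genes = len(transporter_genes)
    return {
        "clusters": len(by_cluster),
        "genes": n_genes,
        "img_subunits": img_tally,
        "abcdb_subunits": abcdb_tally,
        "covered_genes": len(covered),
        "covered_genes_percent": format_percent(len(covered), n_genes) if n_genes else "0.0",
        "fully_covered_clusters": len(fully),
        "fully_covered_cluster_ids": sorted(fully),
        "cut2_genes": len(cut2),
        "cut2_clusters": len({g.cluster_id for g in cut2}),
    }


# ---------------------------------------------------------------------------
# pathway completeness


def load_pathway_roles(path=None) -> dict[str, list[tuple[str, list[str]]]]:
    """The shipped pathway -> ordered (role, product patterns) catalog."""
    src = (
        resources.files("proteopolish.data").joinpath("pathway_roles.tsv")
        if path is None
        else path
    )
    df = pd.read_csv(src, sep="\t", comment="#")
    catalog: dict[str, list[tuple[str, list[str]]]] = {}
    for row in df.itertuples(index=False):
        catalog.setdefault(str(row.pathway), []).append(
            (str(row.role), [p.strip().lower() for p in str(row.patterns).split(";")])
        )
    return catalog


def pathway_presence(
    genome: GenomeRecord,
    pathway_definitions: Optional[Mapping[str, Sequence[str]]] = None,
    coverage_table=None,
    catalog: Optional[dict] = None,
) -> pd.DataFrame:
    """Presence/support matrix: one row per pathway step.

    ``gene_present`` — any annotated product matches the role's patterns;
    ``peptide_support`` — present with coverage > 0%; ``missing`` flags
    steps with no annotated gene at all (pathway holes such as an absent
    transaldolase).  ``pathway_definitions`` maps pathway name to an ordered
    list of role symbols (defaults to the shipped catalog's own pathways);
    a role symbol absent from the catalog is an error.
    """
    cat = catalog if catalog is not None else load_pathway_roles()
    role_patterns = {role: pats for steps in cat.values() for role, pats in steps}
    if pathway_definitions is None:
        definitions = {pw: [role for role, _ in steps] for pw, steps in cat.items()}
    else:
        definitions = {pw: list(roles) for pw, roles in pathway_definitions.items()}
    cov = _coverage_lookup(coverage_table) if coverage_table is not None else {}
    rows = []
    for pw, roles in definitions.items():
        for role in roles:
            if role not in role_patterns:
                raise ValidationError(f"unknown pathway role symbol {role!r}")
            pats = role_patterns[role]
            loci = [
                f.locus_tag
                for f in genome.cds_features()
                if any(p in f.product.lower() for p in pats)
            ]
            present = bool(loci)
            support = any(float(cov.get(t, 0.0)) > 0 for t in loci)
            rows.append(
                (pw, role, present, ",".join(loci), present and support, not present)
            )
    return pd.DataFrame(
        rows,
        columns=["pathway", "role", "gene_present", "loci", "peptide_support", "missing"],
    )
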