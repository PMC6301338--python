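"""Deterministic synthetic BEL corpora, resource networks and omics tables.

Every generator takes an explicit seed and returns, alongside its
artifact, a *ground-truth ledger* recording what was planted (node/edge
counts, contradictory pairs, negative-correlation triangles, citation and
annotation assignments), so motif finders, seed methods and the diffusion
workflow can be checked against planted truth rather than re-derived
truth.

The corpus generator actively avoids planting motifs by accident: a
random causal statement never reverses the sign of an existing node pair,
and random negative correlations never close a triangle, so the ledger's
motif lists are exact.

The staged omics generator emulates a disease-progression study design:
per-gene score trajectories across ordered stages (early/moderate/severe
by default) are drawn from archetype mean profiles (rising, falling,
late-falling, flat, elevated) scaled by an effect size, plus Gaussian
noise.  Real differential-expression data additionally carry
heteroskedastic noise, missing genes and correlated errors that this
generator does not emulate.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .diffusion import OmicsTable
from .graph_model import Citation, Edge, KnowledgeNetwork, Node

__all__ = [
    "CorpusSpec",
    "OmicsSpec",
    "generate_corpus",
    "generate_family_resource",
    "generate_staged_omics",
]

_AUTHOR_POOL = tuple(f"Author {c}" for c in "ABCDEFGHIJ")

_DEFAULT_MIXTURE = {
    "increases": 0.30,
    "decreases": 0.20,
    "directlyIncreases": 0.06,
    "directlyDecreases": 0.04,
    "association": 0.08,
    "positiveCorrelation": 0.10,
    "negativeCorrelation": 0.12,
    "isA": 0.05,
    "hasMember": 0.05,
}


@dataclass
class CorpusSpec:
    """Parameters of a synthetic curated corpus.

    ``p_contradiction`` / ``p_neg_corr_triangle`` are per-statement-slot
    probabilities of planting a contradictory pair (two opposing causal
    statements) or an all-negative correlation triangle (three
    statements).
    """

    n_genes: int = 30
    n_statements: int = 60
    namespaces: Optional[dict[str, list[str]]] = None
    relation_mixture: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIXTURE)
    )
    p_contradiction: float = 0.0
    p_neg_corr_triangle: float = 0.0
    n_bioprocesses: int = 0
    n_pathologies: int = 0
    p_bioprocess_target: float = 0.3
    n_citations: int = 10
    annotations: dict[str, list[str]] = field(
        default_factory=lambda: {"CellLine": ["A549", "HEK293"], "Tissue": ["cortex", "hippocampus"]}
    )
    p_annotation: float = 0.5
    p_activity: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.relation_mixture.values()) > 1.0 + 1e-9:
            raise ValueError("relation mixture probabilities must sum to <= 1")
        if not (0 <= self.p_contradiction <= 1 and 0 <= self.p_neg_corr_triangle <= 1):
            raise ValueError("planting probabilities must lie in [0, 1]")

    def resolved_namespaces(self) -> dict[str, list[str]]:
        if self.namespaces is not None:
            ns = {k: sorted(v) for k, v in self.namespaces.items()}
        else:
            ns = {"HGNC": [f"GENE{i:03d}" for i in range(1, self.n_genes + 1)]}
        if self.n_bioprocesses:
            ns.setdefault("GO", [f"process_{i}" for i in range(1, self.n_bioprocesses + 1)])
        if self.n_pathologies:
            ns.setdefault("MESH", [f"Disease_{i}" for i in range(1, self.n_pathologies + 1)])
        return ns


def _bel_string(value: str) -> str:
    return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _citation_line(citation: Citation) -> str:
    fields = [citation.db_type, citation.name, citation.reference, citation.date or "",
              "|".join(citation.authors)]
    while len(fields) > 3 and fields[-1] == "":
        fields.pop()
    return "SET Citation = {" + ", ".join(_bel_string(f) for f in fields) + "}"


def generate_corpus(spec: CorpusSpec) -> tuple[str, dict]:
    """Emit a valid BEL script and its ground-truth ledger.

    The script parses with zero error-severity issues; the ledger records
    true node/edge/statement counts, every planted contradictory pair and
    negative-correlation triangle, and the citation/author/annotation
    assignment of every statement.  Deterministic given ``spec.seed``.
    """
    rng = random.Random(spec.seed)
    namespaces = spec.resolved_namespaces()

    proteins = [
        Node("protein", ns, name)
        for ns in sorted(namespaces)
        if ns not in ("GO", "MESH")
        for name in namespaces[ns]
    ]
    bioprocesses = [
        Node("bioprocess", "GO", name) for name in namespaces.get("GO", [])
    ]
    pathologies = [
        Node("pathology", "MESH", name) for name in namespaces.get("MESH", [])
    ]
    if len(proteins) < 3:
        raise ValueError("need at least three entity terms")

    citations = []
    for i in range(max(spec.n_citations, 1)):
        n_authors = rng.randint(1, 3)
        authors = tuple(sorted(rng.sample(_AUTHOR_POOL, n_authors)))
        citations.append(
            Citation("PubMed", str(20000000 + i), f"Article {i}", authors, None)
        )

    # bookkeeping that keeps planted motifs exact
    pair_signs: dict[tuple[Node, Node], set[int]] = {}
    neg_corr: dict[Node, set[Node]] = {}
    planted_pairs: list[tuple[Node, Node]] = []
    planted_triangles: list[tuple[Node, Node, Node]] = []

    relations = sorted(spec.relation_mixture)
    weights = [spec.relation_mixture[r] for r in relations]

    def sample_pair(candidates: Sequence[Node]) -> tuple[Node, Node]:
        u, v = rng.sample(candidates, 2)
        return u, v

    raw_statements: list[dict] = []  # subject, relation, object, activity flags

    def push(subject: Node, relation: str, obj: Node, obj_activity: bool = False) -> None:
        raw_statements.append(
            {"subject": subject, "relation": relation, "object": obj,
             "object_activity": obj_activity}
        )

    slots = 0
    while slots < spec.n_statements:
        roll = rng.random()
        if roll < spec.p_contradiction:
            for _ in range(50):
                u, v = sample_pair(proteins)
                if (u, v) not in pair_signs:
                    break
            else:
                slots += 1
                continue
            activity = rng.random() < spec.p_activity
            push(u, "increases", v, activity)
            push(u, "decreases", v, activity)
            pair_signs[(u, v)] = {1, -1}
            planted_pairs.append((u, v))
            slots += 1
            continue
        if roll < spec.p_contradiction + spec.p_neg_corr_triangle:
            for _ in range(50):
                a, b, c = rng.sample(proteins, 3)
                if all(n not in neg_corr for n in (a, b, c)):
                    break
            else:
                slots += 1
                continue
            for x, y in ((a, b), (b, c), (c, a)):
                push(x, "negativeCorrelation", y)
                neg_corr.setdefault(x, set()).add(y)
                neg_corr.setdefault(y, set()).add(x)
            planted_triangles.append(tuple(sorted((a, b, c))))
            slots += 1
            continue

        relation = rng.choices(relations, weights=weights, k=1)[0]
        if relation in ("increases", "directlyIncreases", "decreases", "directlyDecreases"):
            sign = 1 if relation in ("increases", "directlyIncreases") else -1
            use_bp = bioprocesses and rng.random() < spec.p_bioprocess_target
            use_path = (
                not use_bp and pathologies and rng.random() < spec.p_bioprocess_target / 2
            )
            for _ in range(50):
                subject = rng.choice(proteins)
                if use_bp:
                    obj = rng.choice(bioprocesses)
                elif use_path:
                    obj = rng.choice(pathologies)
                else:
                    obj = rng.choice(proteins)
                if obj is subject:
                    continue
                if -sign not in pair_signs.get((subject, obj), set()):
                    break
            else:
                slots += 1
                continue
            pair_signs.setdefault((subject, obj), set()).add(sign)
            push(subject, relation, obj, rng.random() < spec.p_activity)
        elif relation == "negativeCorrelation":
            for _ in range(50):
                u, v = sample_pair(proteins)
                if v in neg_corr.get(u, set()):
                    continue
                if neg_corr.get(u, set()) & neg_corr.get(v, set()):
                    continue  # would close a triangle
                break
            else:
                slots += 1
                continue
            push(u, relation, v)
            neg_corr.setdefault(u, set()).add(v)
            neg_corr.setdefault(v, set()).add(u)
        else:
            u, v = sample_pair(proteins)
            push(u, relation, v)
        slots += 1

    # render the script and the ledger
    annotation_keys = sorted(spec.annotations)
    lines = [
        'SET DOCUMENT Name = "Synthetic corpus"',
        f'SET DOCUMENT Version = "{spec.seed}"',
    ]
    for keyword in sorted(namespaces):
        terms = ", ".join(_bel_string(t) for t in sorted(namespaces[keyword]))
        lines.append(f"DEFINE NAMESPACE {keyword} AS LIST {{{terms}}}")
    for keyword in annotation_keys:
        values = ", ".join(_bel_string(v) for v in sorted(spec.annotations[keyword]))
        lines.append(f"DEFINE ANNOTATION {keyword} AS LIST {{{values}}}")

    ledger_statements = []
    nodes_used: set[Node] = set()
    edge_keys: set[tuple] = set()
    for i, raw in enumerate(raw_statements):
        citation = rng.choice(citations)
        evidence = f"Evidence sentence {i}."
        annotations: dict[str, tuple[str, ...]] = {}
        for key in annotation_keys:
            if rng.random() < spec.p_annotation:
                count = rng.randint(1, min(2, len(spec.annotations[key])))
                annotations[key] = tuple(sorted(rng.sample(sorted(spec.annotations[key]), count)))
        lines.append("")
        lines.append(_citation_line(citation))
        lines.append(f"SET Evidence = {_bel_string(evidence)}")
        for key in sorted(annotations):
            values = ", ".join(_bel_string(v) for v in annotations[key])
            lines.append(f"SET {key} = {{{values}}}")
        obj_bel = raw["object"].as_bel()
        if raw["object_activity"]:
            obj_bel = f"act({obj_bel})"
        lines.append(f"{raw['subject'].as_bel()} {raw['relation']} {obj_bel}")
        lines.append("UNSET ALL")

        nodes_used.add(raw["subject"])
        nodes_used.add(raw["object"])
        qualifiers = ("object_activity",) if raw["object_activity"] else ()
        edge_keys.add(
            (raw["subject"], raw["object"], raw["relation"], citation.reference,
             evidence, tuple(sorted(annotations.items())), qualifiers)
        )
        ledger_statements.append(
            {
                "subject": raw["subject"].as_bel(),
                "relation": raw["relation"],
                "object": raw["object"].as_bel(),
                "object_activity": raw["object_activity"],
                "citation": citation.reference,
                "authors": list(citation.authors),
                "annotations": {k: list(v) for k, v in sorted(annotations.items())},
                "evidence": evidence,
            }
        )

    ledger = {
        "seed": spec.seed,
        "n_statements": len(raw_statements),
        "n_nodes": len(nodes_used),
        "n_edges": len(edge_keys),
        "nodes": sorted(n.as_bel() for n in nodes_used),
        "contradictory_pairs": sorted(
            [u.as_bel(), v.as_bel()] for u, v in planted_pairs
        ),
        "neg_corr_triangles": sorted(
            [a.as_bel(), b.as_bel(), c.as_bel()] for a, b, c in planted_triangles
        ),
        "citations": {
            c.reference: {"name": c.name, "authors": list(c.authors)} for c in citations
        },
        "statements": ledger_statements,
    }
    return "\n".join(lines) + "\n", ledger


def generate_family_resource(
    families: Mapping[str, Sequence[str]],
    namespace: str = "HGNC",
    family_namespace: str = "FPLX",
) -> KnowledgeNetwork:
    """A resource network of ``hasMember`` edges from family nodes to
    member protein nodes."""
    network = KnowledgeNetwork(name="family resource")
    for family in sorted(families):
        family_node = Node("protein", family_namespace, family)
        network.add_node(family_node)
        for member in sorted(families[family]):
            network.add_edge(
                Edge(family_node, Node("protein", namespace, member), "hasMember")
            )
    return network


@dataclass
class OmicsSpec:
    """Staged differential-expression design with trajectory archetypes.

    ``archetypes`` maps archetype name to per-stage mean profiles (in
    log2-fold-change units before ``effect_size`` scaling); ``noise_sd``
    is the per-observation Gaussian noise standard deviation.
    """

    stages: tuple[str, ...] = ("early", "moderate", "severe")
    archetypes: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "rising": (0.0, 1.0, 2.0),
            "falling": (0.0, -1.0, -2.0),
            "late_fall": (0.0, 0.0, -1.5),
            "flat": (0.0, 0.0, 0.0),
            "elevated": (1.5, 1.5, 1.5),
        }
    )
    effect_size: float = 2.0
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("need at least one stage")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for name, profile in self.archetypes.items():
            if len(profile) != len(self.stages):
                raise ValueError(f"archetype {name!r} length != number of stages")


def generate_staged_omics(
    spec: OmicsSpec,
    genes: Sequence[tuple[str, str]],
    assignments: Optional[Mapping[tuple[str, str], str]] = None,
) -> tuple[list[OmicsTable], dict[tuple[str, str], str]]:
    """One omics table per stage plus the true per-gene archetype labels.

    Each gene draws an archetype (uniformly, unless ``assignments`` pins
    it) and per-stage scores = effect_size · archetype mean + Gaussian
    noise.  Deterministic given ``spec.seed``.
    """
    rng = random.Random(spec.seed)
    archetype_names = sorted(spec.archetypes)
    truth: dict[tuple[str, str], str] = {}
    scores: dict[tuple[str, str], list[float]] = {}
    for gene in genes:
        gene = (gene[0], gene[1])
        if assignments is not None and gene in assignments:
            archetype = assignments[gene]
            if archetype not in spec.archetypes:
                raise ValueError(f"unknown archetype {archetype!r}")
        else:
            archetype = rng.choice(archetype_names)
        truth[gene] = archetype
        profile = spec.archetypes[archetype]
        scores[gene] = [
            spec.effect_size * mean + rng.gauss(0.0, spec.noise_sd)
            for mean in profile
        ]
    tables = []
    ordered = sorted(scores)
    for stage_index, stage in enumerate(spec.stages):
        tables.append(
            OmicsTable.from_rows(
                [(ns, name, scores[(ns, name)][stage_index]) for ns, name in ordered],
                label=stage,
            )
        )
    return tables, truth
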