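"""End-to-end disease-progression workflow on a synthetic corpus.

This module scripts the package's worked example: a disease-specific
corpus is compiled, seeded down to four annotated candidate-mechanism
subgraphs, pre-processed by the standard pipeline (member enrichment,
removal of mouse/rat namespace nodes and pathology hubs, causal
extraction, central-dogma origin enrichment, variant and gene
collapsing), overlaid with three-stage differential-expression tables,
diffused, and the resulting per-stage biological-process heats clustered
with K-means (K = 5).

The synthetic corpus plants a trajectory archetype per biological
process: each process is driven by a dedicated set of genes whose staged
scores follow that archetype, so recovered clusters can be scored
against planted truth with a best-assignment label agreement.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .bel_io import parse_bel_document
from .diffusion import OmicsTable, cluster_trajectories, diffuse, map_scores, process_heats
from .fixtures import OmicsSpec, generate_family_resource, generate_staged_omics
from .graph_model import KnowledgeNetwork, Node, compile as compile_network
from .query import Query, SeedSpec, run_query

__all__ = ["ScenarioData", "ScenarioResult", "generate_scenario", "run_scenario",
           "label_agreement", "SCENARIO_PIPELINE"]

SUBGRAPH_NAMES = (
    "lipoprotein subgraph",
    "GABA subgraph",
    "notch signaling subgraph",
    "reactive oxygen species subgraph",
)

#: The pre-processing pipeline of the worked example, in order.
SCENARIO_PIPELINE: tuple[tuple[str, dict], ...] = (
    ("enrich_members", {"resource": "families"}),
    ("delete_namespace_nodes", {"namespaces": ["MGI", "RGD"]}),
    ("remove_pathologies", {}),
    ("extract_causal", {}),
    ("enrich_protein_rna_origins", {}),
    ("collapse_variants", {}),
    ("collapse_to_genes", {}),
)


@dataclass
class ScenarioData:
    bel_text: str
    family_resource: KnowledgeNetwork
    omics_tables: list[OmicsTable]
    bp_truth: dict[str, str]  # bioprocess name -> archetype
    gene_truth: dict[tuple[str, str], str]
    subgraphs: tuple[str, ...]
    stages: tuple[str, ...]


@dataclass
class ScenarioResult:
    heats: pd.DataFrame  # index: bioprocess name; columns: stages + "cluster"
    labels: dict[str, int]
    truth: dict[str, str]
    agreement: float
    network: KnowledgeNetwork


def generate_scenario(
    seed: int,
    n_bp_per_archetype: int = 4,
    genes_per_bp: int = 3,
    noise_sd: float = 0.25,
) -> ScenarioData:
    """Build the synthetic progression corpus with planted archetypes.

    Per archetype, ``n_bp_per_archetype`` biological processes are each
    driven (``increases``) by ``genes_per_bp`` dedicated genes whose
    staged omics scores follow the archetype.  The corpus additionally
    carries family, mouse/rat, pathology, correlative and variant
    statements so every pipeline step has work to do, plus unannotated
    distractor edges that the annotation seeding must drop.
    """
    omics_spec = OmicsSpec(noise_sd=noise_sd, seed=seed)
    archetypes = sorted(omics_spec.archetypes)
    rng = random.Random(seed + 1)

    lines = [
        'SET DOCUMENT Name = "Progression scenario"',
        f'SET DOCUMENT Version = "{seed}"',
    ]
    genes: list[str] = []
    bp_truth: dict[str, str] = {}
    bp_genes: dict[str, list[str]] = {}
    counter = 0
    for archetype in archetypes:
        for i in range(n_bp_per_archetype):
            bp_name = f"BP_{archetype}_{i}"
            bp_truth[bp_name] = archetype
            members = []
            for _ in range(genes_per_bp):
                counter += 1
                members.append(f"GENE{counter:03d}")
            bp_genes[bp_name] = members
            genes.extend(members)

    hgnc_terms = sorted(genes + ["EXTRA1", "EXTRA2", "EXTRA3"])
    go_terms = sorted(bp_truth)
    lines += [
        "DEFINE NAMESPACE HGNC AS LIST {" + ", ".join(f'"{t}"' for t in hgnc_terms) + "}",
        "DEFINE NAMESPACE GO AS LIST {" + ", ".join(f'"{t}"' for t in go_terms) + "}",
        'DEFINE NAMESPACE MGI AS LIST {"Mouse1", "Mouse2"}',
        'DEFINE NAMESPACE RGD AS LIST {"Rat1", "Rat2"}',
        'DEFINE NAMESPACE MESH AS LIST {"Neurodegeneration"}',
        'DEFINE NAMESPACE FPLX AS LIST {"FamilyA", "FamilyB"}',
        "DEFINE ANNOTATION Subgraph AS LIST {"
        + ", ".join(f'"{s}"' for s in SUBGRAPH_NAMES)
        + "}",
    ]

    def statement(subject: str, relation: str, obj: str, subgraph: str | None) -> None:
        pmid = str(30000000 + rng.randint(0, 20))
        lines.append("")
        lines.append(f'SET Citation = {{"PubMed", "Scenario article", "{pmid}"}}')
        lines.append(f'SET Evidence = "Scenario evidence {len(lines)}."')
        if subgraph is not None:
            lines.append(f'SET Subgraph = {{"{subgraph}"}}')
        lines.append(f"{subject} {relation} {obj}")
        lines.append("UNSET ALL")

    for bp_index, bp_name in enumerate(sorted(bp_truth)):
        subgraph = SUBGRAPH_NAMES[bp_index % len(SUBGRAPH_NAMES)]
        for gene_index, gene in enumerate(bp_genes[bp_name]):
            # one driver per process carries a phosphorylation variant so
            # the variant-collapse step has real work
            term = (
                f'p(HGNC:{gene}, pmod(Ph))' if gene_index == 0 else f"p(HGNC:{gene})"
            )
            statement(term, "increases", f"bp(GO:{bp_name})", subgraph)

    # family statements (causal, annotated) + resource with their members
    family_members = {
        "FamilyA": [bp_genes[sorted(bp_truth)[0]][0], bp_genes[sorted(bp_truth)[1]][0]],
        "FamilyB": [bp_genes[sorted(bp_truth)[2]][0]],
    }
    statement("p(FPLX:FamilyA)", "increases", f"p(HGNC:{family_members['FamilyA'][0]})",
              SUBGRAPH_NAMES[0])
    statement("p(FPLX:FamilyB)", "increases", f"p(HGNC:{family_members['FamilyB'][0]})",
              SUBGRAPH_NAMES[1])
    # mouse/rat statements the pipeline must delete
    statement("p(MGI:Mouse1)", "increases", f"p(HGNC:{genes[0]})", SUBGRAPH_NAMES[0])
    statement("p(RGD:Rat1)", "decreases", f"p(HGNC:{genes[1]})", SUBGRAPH_NAMES[1])
    # pathology hub the pipeline must remove
    statement(f"p(HGNC:{genes[2]})", "increases", "path(MESH:Neurodegeneration)",
              SUBGRAPH_NAMES[2])
    # correlative edges the causal extraction must drop
    statement(f"p(HGNC:{genes[3]})", "positiveCorrelation", f"p(HGNC:{genes[4]})",
              SUBGRAPH_NAMES[3])
    # unannotated distractors the seeding must drop
    statement("p(HGNC:EXTRA1)", "increases", "p(HGNC:EXTRA2)", None)
    statement("p(HGNC:EXTRA2)", "decreases", "p(HGNC:EXTRA3)", None)

    resource = generate_family_resource(family_members, namespace="HGNC")

    gene_assignments = {
        ("HGNC", gene): bp_truth[bp_name]
        for bp_name, members in bp_genes.items()
        for gene in members
    }
    tables, gene_truth = generate_staged_omics(
        omics_spec,
        sorted(gene_assignments),
        assignments=gene_assignments,
    )
    return ScenarioData(
        bel_text="\n".join(lines) + "\n",
        family_resource=resource,
        omics_tables=tables,
        bp_truth=bp_truth,
        gene_truth=gene_truth,
        subgraphs=SUBGRAPH_NAMES,
        stages=omics_spec.stages,
    )


def label_agreement(truth: dict, predicted: dict) -> float:
    """Best-assignment accuracy between two labelings of the same keys."""
    keys = sorted(truth)
    true_names = sorted(set(truth.values()))
    pred_names = sorted(set(predicted[k] for k in keys))
    confusion = np.zeros((len(true_names), len(pred_names)))
    for key in keys:
        confusion[true_names.index(truth[key]), pred_names.index(predicted[key])] += 1
    rows, cols = linear_sum_assignment(-confusion)
    return confusion[rows, cols].sum() / len(keys)


def run_scenario(seed: int, k: int = 5, **scenario_kwargs) -> ScenarioResult:
    """Execute the full workflow and score cluster recovery.

    Returns the per-stage biological-process heat table with cluster
    labels and the best-assignment agreement between recovered clusters
    and planted archetypes.
    """
    data = generate_scenario(seed, **scenario_kwargs)
    document = parse_bel_document(data.bel_text)
    if document.errors:
        raise RuntimeError(f"scenario corpus failed to parse: {document.errors[:3]}")
    network = compile_network(document)
    catalog = {"scenario": network, "families": data.family_resource}
    query = Query(
        network_ids=["scenario"],
        seeds=[SeedSpec("annotations", {"filters": {"Subgraph": list(data.subgraphs)}})],
        pipeline=[(name, dict(args)) for name, args in SCENARIO_PIPELINE],
    )
    processed = run_query(query, catalog)

    heat_maps: list[dict[Node, float]] = []
    for table in data.omics_tables:
        state = map_scores(processed, table)
        result = diffuse(processed, state)
        heat_maps.append(process_heats(result, processed))

    labels = cluster_trajectories(heat_maps, k=k, seed=seed)
    named_labels = {node.name: label for node, label in labels.items()}
    truth = {name: data.bp_truth[name] for name in named_labels}
    agreement = label_agreement(truth, named_labels)

    bp_nodes = sorted(labels)
    frame = pd.DataFrame(
        [
            [heat_map.get(node, 0.0) for heat_map in heat_maps]
            for node in bp_nodes
        ],
        index=[node.name for node in bp_nodes],
        columns=list(data.stages),
    )
    frame["cluster"] = [labels[node] for node in bp_nodes]
    return ScenarioResult(
        heats=frame,
        labels=named_labels,
        truth=truth,
        agreement=agreement,
        network=processed,
    )
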