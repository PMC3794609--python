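"""Synthetic fixtures with planted coordinated expression.

The generator emulates the four inputs the pipeline consumes: a network of
designated hub stars plus random background edges, a tissue-blocked
expression matrix, a gold standard naming each planted hub's tissue
category, and a tissue -> category map (identity by default).

Planting is latent-factor based, not mean-shift based: within a hub's
planted tissue, the hub and every interactor equal ``beta * f_j + noise``
with a shared standard-normal factor f_j per sample, so their population
correlation is

    expected_pcc(beta, sd) = beta^2 / (beta^2 + sd^2),

while every tissue mean stays zero.  Coordinated-expression scoring sees
the planting; a mean-based single-protein t-test does not, which is what
lets co-expression ranking beat the baseline by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionCompendium, TissueCategoryMap
from .benchmark import GoldStandard
from .network import InteractionNetwork, ProteinComplex

import networkx as nx

__all__ = ["PlantingSpec", "generate_fixture", "expected_pcc", "write_fixture"]


@dataclass
class PlantingSpec:
    """Parameters of a planted-coordination fixture.

    ``planted`` maps hub id -> (tissue label, beta >= 0); hubs are named
    ``HUB00``.. and tissues ``tissue00``..  ``samples_per_tissue`` may be a
    single int or one int per tissue (unequal counts exercise the
    sample-size correction).  Default planting couples every hub to one
    tissue, cycling through tissues, at ``beta``.
    """

    n_genes: int = 120
    n_tissues: int = 6
    samples_per_tissue: int | list[int] = field(default_factory=lambda: [12, 13, 14, 15, 16, 17])
    n_hubs: int = 8
    interactors_per_hub: int = 6
    beta: float = 3.0
    planted: dict[str, tuple[str, float]] | None = None
    noise_sd: float = 1.0
    baseline_sd: float = 1.0
    n_background_edges: int = 60
    seed: int = 0

    def hub_names(self) -> list[str]:
        return [f"HUB{i:02d}" for i in range(self.n_hubs)]

    def tissue_names(self) -> list[str]:
        return [f"tissue{i:02d}" for i in range(self.n_tissues)]

    def samples_per(self) -> list[int]:
        if isinstance(self.samples_per_tissue, int):
            return [self.samples_per_tissue] * self.n_tissues
        if len(self.samples_per_tissue) != self.n_tissues:
            raise ValueError("samples_per_tissue length must equal n_tissues")
        return list(self.samples_per_tissue)

    def resolved_planting(self) -> dict[str, tuple[str, float]]:
        if self.planted is not None:
            tissues = set(self.tissue_names())
            hubs = set(self.hub_names())
            for h, (t, b) in self.planted.items():
                if h not in hubs or t not in tissues or b < 0:
                    raise ValueError(f"invalid planting entry {h!r} -> ({t!r}, {b})")
            return dict(self.planted)
        tissues = self.tissue_names()
        return {
            h: (tissues[i % self.n_tissues], self.beta)
            for i, h in enumerate(self.hub_names())
        }

    def validate(self) -> None:
        if self.noise_sd <= 0 or self.baseline_sd <= 0:
            raise ValueError("noise_sd and baseline_sd must be > 0")
        needed = self.n_hubs * (1 + self.interactors_per_hub)
        if self.n_genes < needed:
            raise ValueError(f"n_genes={self.n_genes} < {needed} hub+interactor genes")
        self.samples_per()
        self.resolved_planting()


def expected_pcc(beta: float, noise_sd: float) -> float:
    """Population hub-interactor correlation under latent-factor planting.

    Both variables are beta * f + e with shared f ~ N(0,1) and independent
    e ~ N(0, noise_sd^2), so cov = beta^2 and var = beta^2 + noise_sd^2.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    return beta**2 / (beta**2 + noise_sd**2)


def generate_fixture(
    spec: PlantingSpec,
) -> tuple[InteractionNetwork, ExpressionCompendium, GoldStandard, TissueCategoryMap]:
    """Generate network, expression, gold standard and category map.

    Everything is a deterministic function of ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    hubs = spec.hub_names()
    interactors = {
        h: [f"{h}_I{j:02d}" for j in range(spec.interactors_per_hub)] for h in hubs
    }
    n_member = spec.n_hubs * (1 + spec.interactors_per_hub)
    background = [f"BG{k:04d}" for k in range(spec.n_genes - n_member)]
    genes = hubs + [g for h in hubs for g in interactors[h]] + background

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for h in hubs:
        graph.add_edges_from((h, g) for g in interactors[h])
    if len(background) >= 2 and spec.n_background_edges:
        for _ in range(spec.n_background_edges):
            a, b = rng.choice(len(background), size=2, replace=False)
            graph.add_edge(background[a], background[b])
    net = InteractionNetwork(graph)

    tissues = spec.tissue_names()
    per = spec.samples_per()
    samples, tissue_of = [], {}
    for t, k in zip(tissues, per):
        for j in range(k):
            s = f"{t}_s{j:02d}"
            samples.append(s)
            tissue_of[s] = t

    gi = {g: i for i, g in enumerate(genes)}
    si = {s: i for i, s in enumerate(samples)}
    values = rng.normal(0.0, spec.baseline_sd, size=(len(genes), len(samples)))
    planting = spec.resolved_planting()
    for h, (t, beta) in planting.items():
        cols = [si[s] for s in samples if tissue_of[s] == t]
        members = [gi[h]] + [gi[g] for g in interactors[h]]
        latent = rng.standard_normal(len(cols))
        noise = rng.normal(0.0, spec.noise_sd, size=(len(members), len(cols)))
        values[np.ix_(members, cols)] = beta * latent[None, :] + noise

    compendium = ExpressionCompendium(
        pd.DataFrame(values, index=genes, columns=samples),
        tissue_of,
        {s: "normal" for s in samples},
    )
    cmap = TissueCategoryMap.identity(tissues)
    gold = GoldStandard(
        tuple(
            (h, f"pseudo-disease-{h}", (cmap[planting[h][0]],))
            for h in hubs
            if h in planting
        )
    )
    return net, compendium, gold, cmap


def planted_complexes(spec: PlantingSpec) -> list[ProteinComplex]:
    """The hub-star complexes the generator plants, without re-extraction."""
    return [
        ProteinComplex(h, tuple(sorted(f"{h}_I{j:02d}" for j in range(spec.interactors_per_hub))))
        for h in spec.hub_names()
    ]


def write_fixture(spec: PlantingSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture in the exact TSV formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, comp, gold, cmap = generate_fixture(spec)
    paths = {
        "network": outdir / "network.tsv",
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "gold": outdir / "gold_standard.tsv",
        "categories": outdir / "tissue_categories.tsv",
    }
    with open(paths["network"], "w") as fh:
        fh.write("# synthetic interaction network\n")
        for e in sorted(tuple(sorted(edge)) for edge in net.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")
    comp.values.to_csv(paths["expression"], sep="\t", float_format="%.8g")
    pd.DataFrame(
        {
            "sample": comp.samples,
            "tissue": [comp.tissue_of[s] for s in comp.samples],
            "condition": [comp.condition_of[s] for s in comp.samples],
        }
    ).to_csv(paths["metadata"], sep="\t", index=False)
    pd.DataFrame(
        {
            "gene": [g for g, _, _ in gold],
            "disease": [d for _, d, _ in gold],
            "tissue_categories": [";".join(cats) for _, _, cats in gold],
        }
    ).to_csv(paths["gold"], sep="\t", index=False)
    pd.DataFrame(
        {
            "tissue": sorted(cmap.category_of),
            "category": [cmap.category_of[t] for t in sorted(cmap.category_of)],
        }
    ).to_csv(paths["categories"], sep="\t", index=False)
    return paths
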