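"""Local molecular networking of MS/MS spectra.

Spectral similarity is the modified cosine: fragment peaks may match either
directly (within a fragment tolerance) or shifted by the difference of the
two precursor masses, so structural analogs differing by one modification
still align.  Intensities are square-root scaled and unit-normalized; the
score is the dot product over a one-to-one peak matching.  The matching is
chosen greedily by descending intensity product, a deterministic
approximation of the optimal assignment (an exhaustive oracle is used in the
test suite for small spectra).

Networks retain edges with score >= min_cosine and >= min_matched matched
peaks, trim oversized connected components by removing their lowest-scoring
edges, and drop components smaller than a minimum cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "MSMSSpectrum",
    "NetworkEdge",
    "MolecularNetwork",
    "modified_cosine",
    "build_network",
    "export_network",
    "load_network",
    "read_mgf",
    "write_mgf",
]


@dataclass
class MSMSSpectrum:
    """An MS/MS spectrum: precursor m/z plus fragment peak list."""

    spectrum_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("fragment intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    score: float
    matched: int


@dataclass
class MolecularNetwork:
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def edges(self) -> list[NetworkEdge]:
        return [
            NetworkEdge(u, v, d["score"], d["matched"])
            for u, v, d in self.graph.edges(data=True)
        ]

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]


def modified_cosine(
    s1: MSMSSpectrum,
    s2: MSMSSpectrum,
    fragment_tol: float = 0.5,
    parent_tol: float = 1.0,
) -> tuple[float, int]:
    """Modified cosine similarity between two MS/MS spectra.

    Peaks match directly within ``fragment_tol`` Da or shifted by the
    precursor mass difference; a one-to-one matching is built greedily by
    descending product of square-root-scaled normalized intensities.
    Returns ``(score in [0, 1], number of matched peaks)``.  ``parent_tol``
    bounds the shift bookkeeping only; precursors further apart still score
    via shifted matches as in the networking convention.
    """
    if len(s1) == 0 or len(s2) == 0:
        return 0.0, 0
    w1 = np.sqrt(s1.intensity)
    w2 = np.sqrt(s2.intensity)
    n1 = np.linalg.norm(w1)
    n2 = np.linalg.norm(w2)
    if n1 == 0 or n2 == 0:
        return 0.0, 0
    w1, w2 = w1 / n1, w2 / n2
    shift = s2.precursor_mz - s1.precursor_mz
    shifts = [0.0] if abs(shift) <= fragment_tol else [0.0, shift]
    pairs = []
    for i in range(len(s1)):
        for j in range(len(s2)):
            for sh in shifts:
                if abs(s1.mz[i] + sh - s2.mz[j]) <= fragment_tol:
                    pairs.append((w1[i] * w2[j], i, j))
                    break
    # greedy one-to-one matching by descending intensity product,
    # deterministic tie-break by peak indices
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used1: set[int] = set()
    used2: set[int] = set()
    score = 0.0
    matched = 0
    for p, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        score += p
        matched += 1
    return float(min(score, 1.0)), matched


def build_network(
    spectra: list[MSMSSpectrum],
    min_cosine: float = 0.65,
    min_matched: int = 6,
    max_component: int = 50,
    min_cluster: int = 2,
    fragment_tol: float = 0.5,
    parent_tol: float = 1.0,
) -> MolecularNetwork:
    """Construct a molecular network from MS/MS spectra.

    All spectrum pairs are scored with the modified cosine; edges with
    score >= min_cosine and matched peaks >= min_matched are retained.
    Components larger than ``max_component`` are trimmed by removing the
    globally lowest-scoring edges (ties broken by lexicographic node ids)
    until the bound holds; components smaller than ``min_cluster`` —
    including singletons — are dropped.
    """
    g = nx.Graph()
    for sp in spectra:
        g.add_node(sp.spectrum_id, precursor_mz=sp.precursor_mz, group=sp.group)
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            score, matched = modified_cosine(
                spectra[i], spectra[j], fragment_tol, parent_tol
            )
            if score >= min_cosine and matched >= min_matched:
                g.add_edge(
                    spectra[i].spectrum_id,
                    spectra[j].spectrum_id,
                    score=round(score, 6),
                    matched=matched,
                )
    # trim oversized components, removing weakest edges first
    def oversized():
        return [c for c in nx.connected_components(g) if len(c) > max_component]

    while oversized():
        comp = oversized()[0]
        edges = sorted(
            g.subgraph(comp).edges(data=True),
            key=lambda e: (e[2]["score"], *sorted((e[0], e[1]))),
        )
        u, v, _ = edges[0]
        g.remove_edge(u, v)
    # drop small clusters and singletons
    for comp in list(nx.connected_components(g)):
        if len(comp) < min_cluster:
            g.remove_nodes_from(comp)
    return MolecularNetwork(graph=g)


def export_network(net: MolecularNetwork, path: str | Path) -> None:
    """Write a network to GraphML (node group tags and edge scores kept)."""
    nx.write_graphml(net.graph, str(path))


def load_network(path: str | Path) -> MolecularNetwork:
    """Read a GraphML network written by :func:`export_network`."""
    return MolecularNetwork(graph=nx.read_graphml(str(path)))


# ---------------------------------------------------------------------------
# MGF peak-list I/O (pyteomics-backed)

def write_mgf(spectra: list[MSMSSpectrum], path: str | Path) -> None:
    from pyteomics import mgf as pymgf

    entries = [
        {
            "m/z array": sp.mz,
            "intensity array": sp.intensity,
            "params": {
                "title": sp.spectrum_id,
                "pepmass": sp.precursor_mz,
                **({"group": sp.group} if sp.group else {}),
            },
        }
        for sp in spectra
    ]
    pymgf.write(entries, str(path), file_mode="w")


def read_mgf(path: str | Path) -> list[MSMSSpectrum]:
    from pyteomics import mgf as pymgf

    spectra = []
    with pymgf.MGF(str(path)) as reader:
        for k, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass", (0.0,))
            spectra.append(
                MSMSSpectrum(
                    spectrum_id=str(params.get("title", f"spectrum_{k}")),
                    precursor_mz=float(pepmass[0] if pepmass else 0.0),
                    mz=np.asarray(entry["m/z array"], dtype=float),
                    intensity=np.asarray(entry["intensity array"], dtype=float),
                    group=str(params.get("group", "")),
                )
            )
    return spectra
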