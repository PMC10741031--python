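"""Classic molecular networking over MS/MS spectra.

Modified-cosine spectral similarity (precursor-mass-shift-aware peak
pairing), thresholded similarity graph with the GNPS top-K mutual-edge
convention, connected components, spectral-library node annotation and
majority-vote component class labelling.

The modified cosine here solves the one-to-one peak pairing *exactly* as a
maximum-weight assignment (scipy ``linear_sum_assignment``) rather than the
common greedy heuristic, so the score is the true optimum over pairings; a
greedy score can only be lower.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from pyteomics import mgf as _mgf
from scipy.optimize import linear_sum_assignment

from .compound_library import LibraryHit, LibraryRecord, search_fragments, search_precursor

__all__ = [
    "MsmsSpectrum",
    "NetworkParams",
    "MolecularNetwork",
    "MgfError",
    "read_mgf",
    "write_mgf",
    "modified_cosine",
    "build_network",
    "annotate_nodes",
    "enhance_component_classes",
    "to_graphml",
]


class MgfError(ValueError):
    """Raised for malformed MGF content, citing the offending block."""


@dataclass(frozen=True)
class MsmsSpectrum:
    """A tandem mass spectrum: precursor m/z plus an m/z-sorted peak list."""

    spectrum_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    rt: Optional[float] = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.size == 0:
            raise ValueError(f"spectrum {self.spectrum_id!r}: empty peak list")
        if mz.size != intensity.size:
            raise ValueError(f"spectrum {self.spectrum_id!r}: mz/intensity length mismatch")
        if not np.all(np.isfinite(mz)) or not np.all(np.isfinite(intensity)):
            raise ValueError(f"spectrum {self.spectrum_id!r}: non-finite peak values")
        if np.any(intensity < 0):
            raise ValueError(f"spectrum {self.spectrum_id!r}: negative intensity")
        order = np.argsort(mz, kind="stable")
        mz = mz[order]
        intensity = intensity[order]
        if np.any(np.diff(mz) <= 0):
            # merge exact duplicates is not attempted; strictly increasing required
            raise ValueError(f"spectrum {self.spectrum_id!r}: duplicate peak m/z")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class NetworkParams:
    """Networking parameters; defaults follow the GNPS classic workflow
    (0.01 Da tolerances as in the source analysis, cosine 0.7, 6 matched
    peaks, top-K 10, component cap 100)."""

    fragment_tol: float = 0.01
    precursor_tol: float = 0.01
    min_cosine: float = 0.7
    min_matched_peaks: int = 6
    top_k: int = 10
    max_component_size: Optional[int] = 100

    def __post_init__(self) -> None:
        if self.fragment_tol <= 0 or self.precursor_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not 0.0 <= self.min_cosine <= 1.0:
            raise ValueError("min_cosine must lie in [0, 1]")


@dataclass
class MolecularNetwork:
    """A thresholded spectral-similarity graph.

    ``graph`` is an undirected networkx graph whose nodes are spectrum ids
    (attributes: precursor_mz, rt, annotation, compound_class, component);
    ``components`` maps component index -> sorted node ids (singletons are
    excluded from component numbering and flagged as orphans).
    """

    graph: nx.Graph
    components: Dict[int, List[str]] = field(default_factory=dict)
    orphans: List[str] = field(default_factory=list)
    params: NetworkParams = field(default_factory=NetworkParams)


# ---------------------------------------------------------------------------
# MGF I/O
# ---------------------------------------------------------------------------

def read_mgf(path: str) -> List[MsmsSpectrum]:
    """Read an MGF file into spectra (one per BEGIN/END IONS block).

    Spectrum ids come from TITLE, falling back to sequential numbering.
    A block without a precursor (PEPMASS) or without peaks raises
    :class:`MgfError` naming the block.
    """
    spectra: List[MsmsSpectrum] = []
    try:
        blocks = list(_mgf.read(path, use_index=False))
    except Exception as exc:  # pyteomics raises assorted parse errors
        raise MgfError(f"malformed MGF {path!r}: {exc}") from exc
    for index, block in enumerate(blocks, start=1):
        params = block.get("params", {})
        title = str(params.get("title", f"spectrum_{index}"))
        pepmass = params.get("pepmass")
        if pepmass is None or pepmass[0] is None:
            raise MgfError(f"MGF block {index} ({title!r}): missing PEPMASS")
        rt = params.get("rtinseconds")
        rt_min = float(rt) / 60.0 if rt is not None else None
        mz = np.asarray(block["m/z array"], dtype=float)
        intensity = np.asarray(block["intensity array"], dtype=float)
        if mz.size == 0:
            raise MgfError(f"MGF block {index} ({title!r}): no peaks")
        spectra.append(MsmsSpectrum(
            spectrum_id=title,
            precursor_mz=float(pepmass[0]),
            mz=mz,
            intensity=intensity,
            rt=rt_min,
        ))
    return spectra


def write_mgf(spectra: Sequence[MsmsSpectrum], path: str) -> None:
    entries = []
    for spec in spectra:
        params = {"title": spec.spectrum_id, "pepmass": spec.precursor_mz}
        if spec.rt is not None:
            params["rtinseconds"] = spec.rt * 60.0
        entries.append({
            "m/z array": spec.mz,
            "intensity array": spec.intensity,
            "params": params,
        })
    _mgf.write(entries, output=path, file_mode="w")


# ---------------------------------------------------------------------------
# Modified cosine
# ---------------------------------------------------------------------------

def _candidate_pairs(
    a: MsmsSpectrum, b: MsmsSpectrum, fragment_tol: float
) -> List[Tuple[int, int]]:
    shift = a.precursor_mz - b.precursor_mz
    pairs = []
    for i, mza in enumerate(a.mz):
        for j, mzb in enumerate(b.mz):
            if abs(mza - mzb) <= fragment_tol or abs(mza - (mzb + shift)) <= fragment_tol:
                pairs.append((i, j))
    return pairs


def modified_cosine(
    a: MsmsSpectrum, b: MsmsSpectrum, fragment_tol: float = 0.01
) -> Tuple[float, int]:
    """Modified cosine similarity and matched-peak count.

    Peaks are pairable directly (|Δm/z| ≤ tol) or after shifting by the
    precursor mass difference.  Intensities are square-root transformed and
    L2-normalized per spectrum, so self-similarity is exactly 1.  The
    one-to-one pairing maximizing the summed intensity products is found
    exactly by linear assignment.
    """
    wa = np.sqrt(a.intensity)
    wb = np.sqrt(b.intensity)
    na = float(np.linalg.norm(wa))
    nb = float(np.linalg.norm(wb))
    if na == 0.0 or nb == 0.0:
        return 0.0, 0
    wa = wa / na
    wb = wb / nb

    pairs = _candidate_pairs(a, b, fragment_tol)
    if not pairs:
        return 0.0, 0

    rows = sorted({i for i, _ in pairs})
    cols = sorted({j for _, j in pairs})
    row_of = {i: r for r, i in enumerate(rows)}
    col_of = {j: c for c, j in enumerate(cols)}
    weight = np.zeros((len(rows), len(cols)))
    for i, j in pairs:
        weight[row_of[i], col_of[j]] = wa[i] * wb[j]
    r_idx, c_idx = linear_sum_assignment(-weight)
    score = 0.0
    matched = 0
    for r, c in zip(r_idx, c_idx):
        if weight[r, c] > 0.0:
            score += weight[r, c]
            matched += 1
    return min(float(score), 1.0), matched


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_network(
    spectra: Sequence[MsmsSpectrum], params: NetworkParams = NetworkParams()
) -> MolecularNetwork:
    """Score all spectrum pairs and build the thresholded molecular network.

    Edges require cosine ≥ ``min_cosine`` and ≥ ``min_matched_peaks`` matched
    peaks, and must rank within both endpoints' ``top_k`` strongest edges
    (the GNPS mutual-neighbour convention).  Components larger than
    ``max_component_size`` are pruned by removing their weakest edges.
    Output is invariant to input order: spectra are processed sorted by id.
    """
    if not spectra:
        raise ValueError("no spectra supplied")
    ids = [s.spectrum_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate spectrum ids")
    ordered = sorted(spectra, key=lambda s: s.spectrum_id)

    graph = nx.Graph()
    for spec in ordered:
        graph.add_node(
            spec.spectrum_id,
            precursor_mz=spec.precursor_mz,
            rt=spec.rt if spec.rt is not None else float("nan"),
        )

    scored: List[Tuple[str, str, float, int]] = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            score, matched = modified_cosine(ordered[i], ordered[j], params.fragment_tol)
            if score >= params.min_cosine and matched >= params.min_matched_peaks:
                scored.append((ordered[i].spectrum_id, ordered[j].spectrum_id, score, matched))

    # top-K mutual filtering
    per_node: Dict[str, List[Tuple[float, str, str, int]]] = {}
    for u, v, score, matched in scored:
        per_node.setdefault(u, []).append((score, u, v, matched))
        per_node.setdefault(v, []).append((score, u, v, matched))
    kept_by: Dict[Tuple[str, str], int] = {}
    for node, edges in per_node.items():
        edges.sort(key=lambda e: (-e[0], e[1], e[2]))
        for score, u, v, matched in edges[: params.top_k]:
            kept_by[(u, v)] = kept_by.get((u, v), 0) + 1
    for u, v, score, matched in scored:
        if kept_by.get((u, v), 0) == 2:
            graph.add_edge(u, v, cosine=float(score), matched_peaks=int(matched))

    if params.max_component_size is not None:
        _prune_components(graph, params.max_component_size)

    network = MolecularNetwork(graph=graph, params=params)
    _number_components(network)
    return network


def _prune_components(graph: nx.Graph, max_size: int) -> None:
    while True:
        oversized = [c for c in nx.connected_components(graph) if len(c) > max_size]
        if not oversized:
            return
        for comp in oversized:
            sub = graph.subgraph(comp)
            weakest = min(
                sub.edges(data=True),
                key=lambda e: (e[2]["cosine"], e[0], e[1]),
            )
            graph.remove_edge(weakest[0], weakest[1])


def _number_components(network: MolecularNetwork) -> None:
    graph = network.graph
    network.components = {}
    network.orphans = []
    comps = [sorted(c) for c in nx.connected_components(graph) if len(c) > 1]
    comps.sort(key=lambda c: c[0])
    for index, comp in enumerate(comps, start=1):
        network.components[index] = comp
        for node in comp:
            graph.nodes[node]["component"] = index
    for node in graph.nodes:
        if graph.degree[node] == 0:
            network.orphans.append(node)
            graph.nodes[node]["component"] = 0
    network.orphans.sort()


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_nodes(
    network: MolecularNetwork,
    library: Sequence[LibraryRecord],
    spectra: Sequence[MsmsSpectrum],
    precursor_tol_ppm: float = 10.0,
    fragment_tol: float = 0.01,
) -> MolecularNetwork:
    """Attach the best library hit (and candidates) to each network node.

    Candidates are the precursor matches within ``precursor_tol_ppm``,
    re-ranked by shared-fragment count against the node's spectrum (isomer
    candidates are retained, not collapsed).
    """
    by_id = {s.spectrum_id: s for s in spectra}
    for node in network.graph.nodes:
        spec = by_id.get(node)
        if spec is None:
            continue
        hits = search_precursor(spec.precursor_mz, library, tol_ppm=precursor_tol_ppm)
        if not hits:
            continue
        ranked = search_fragments(
            list(spec.mz),
            [h.record for h in hits],
            tol=fragment_tol,
            min_shared=0,
            precursor_mz=spec.precursor_mz,
        )
        best = ranked[0]
        network.graph.nodes[node]["annotation"] = best.record.record_id
        network.graph.nodes[node]["annotation_name"] = best.record.name
        network.graph.nodes[node]["compound_class"] = best.record.compound_class
        network.graph.nodes[node]["candidates"] = [h.record.record_id for h in ranked]
    return network


def enhance_component_classes(network: MolecularNetwork) -> Dict[int, str]:
    """Majority-vote class label per component (≥50% of annotated nodes).

    Components with no annotated node are "unclassified".  Unannotated nodes
    inside a labelled component inherit the label as ``propagated_class``
    (propagated, not asserted).
    """
    labels: Dict[int, str] = {}
    for index, nodes in network.components.items():
        votes: Dict[str, int] = {}
        annotated = 0
        for node in nodes:
            cls = network.graph.nodes[node].get("compound_class")
            if cls is not None:
                annotated += 1
                votes[cls] = votes.get(cls, 0) + 1
        label = "unclassified"
        if annotated:
            top_class, top_votes = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
            if top_votes * 2 >= annotated:
                label = top_class
        labels[index] = label
        for node in nodes:
            network.graph.nodes[node]["component_class"] = label
            if label != "unclassified" and "compound_class" not in network.graph.nodes[node]:
                network.graph.nodes[node]["propagated_class"] = label
    return labels


def to_graphml(network: MolecularNetwork, path: str) -> None:
    """Write the network as GraphML (list attributes flattened to strings)."""
    export = nx.Graph()
    for node, data in network.graph.nodes(data=True):
        attrs = {}
        for key, value in data.items():
            if isinstance(value, (list, tuple)):
                attrs[key] = ";".join(str(v) for v in value)
            elif value is None:
                continue
            else:
                attrs[key] = value
        export.add_node(node, **attrs)
    for u, v, data in network.graph.edges(data=True):
        export.add_edge(u, v, **data)
    nx.write_graphml(export, path)
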