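"""Diagnostic-fragment classification and evidence integration for
phenolcarboxylic/tannic constituents.

The classifier encodes the cleavage behaviour of the standard constituents
as prioritized diagnostic rules over MS/MS fragment ions and neutral losses:

* chebulic ellagitannins expose the chebuloyl anhydride ion at m/z 337.0201
  with its dehydration/decarboxylation cascade (319.0090 / 293.0303 /
  275.0200), methylated chebulate ions (351.0345 / 365.0502) and, for the
  glycosylated series, chebulate ester companion ions (205.0506, 193.0141,
  249.0401, 231.0290);
* ellagitannins release the HHDP/ellagic ion at 300.9990 (flavogallonic
  450.9940, HHDP-glucose 481.0663) or its dehydro/decarboxy relatives
  (298.9832, 270.9880);
* gallotannins show the galloyl pair 169.0137/125.0243 together with
  galloyl-series neutral losses from the precursor (gallic acid 170.0215,
  galloyl 152.0110, ketene 42.0106, hexose 162.0528, hexitol 164.0685) or
  glucose cross-ring/ester ions (313.0565, 271.0459, 211.0243);
* free phenolcarboxylic acids show galloyl, shikimate (93.0344), gallate
  ester (124.0166), free chebulic-acid or urolithin/brevifolin fragments at
  small precursor mass, without glycosyl evidence.

Higher-priority rules pre-empt lower ones (chebuloyl > HHDP > galloyl), so a
compound showing both 337.0201 and 300.9990 (e.g. chebulagic acid) is
called a chebulic ellagitannin.

Also here: homolog inference from precursor mass differences, measured vs
predicted collision-cross-section comparison, and the integration of the
evidence streams (standard/library/diagnostic/network/homolog/CCS) into one
annotation per feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx

from .chem_mass import DEFAULT_MASS_DELTAS, MassDelta, annotate_mass_difference
from .compound_library import LibraryHit, LibraryRecord, search_fragments, search_precursor
from .msms_networking import (
    MolecularNetwork,
    MsmsSpectrum,
    NetworkParams,
    annotate_nodes,
    build_network,
    enhance_component_classes,
)

__all__ = [
    "DiagnosticRule",
    "DEFAULT_RULES",
    "CHEBULOYL_FAMILY_IONS",
    "AnnotationResult",
    "CcsComparison",
    "classify_spectrum",
    "infer_homolog",
    "compare_ccs",
    "integrate_evidence",
    "annotate_run",
    "class_count_summary",
    "load_rules",
    "save_rules",
    "write_annotations_tsv",
]

UNCLASSIFIED = "unclassified"

# Diagnostic ions of the chebuloyl/chebulate family.  Any chebulic-
# ellagitannin call must be traceable to at least one of these (soundness).
CHEBULOYL_FAMILY_IONS = (
    337.0201,  # chebuloyl anhydride
    319.0090,  # - H2O
    293.0303,  # - CO2
    275.0200,  # - H2O - CO2
    351.0345,  # methyl chebulate anhydride
    365.0502,  # dimethyl chebulate anhydride
    205.0506, 193.0141, 249.0401, 231.0290,  # chebulate ester companions
    203.0344, 337.0560, 409.0770,            # chebulanin family
    435.0556,                                # chebulanin-derivative series
)


@dataclass(frozen=True)
class DiagnosticRule:
    """One prioritized marker-ion rule.

    ``marker_ions`` must match at least ``required_count`` query fragments;
    ``companion_ions`` (if any) must additionally match
    ``companion_required`` fragments.  ``neutral_losses`` name entries of the
    mass-delta catalog: the rule condition is that some fragment sits at
    ``precursor − delta`` for at least one named loss.  ``precursor_min`` /
    ``precursor_max`` bound the precursor m/z, and ``veto_losses`` names
    losses whose presence forbids the rule (used to keep glycosides out of
    the free-acid rule).
    """

    rule_id: str
    implied_class: str
    priority: int
    marker_ions: Tuple[float, ...] = ()
    required_count: int = 1
    companion_ions: Tuple[float, ...] = ()
    companion_required: int = 0
    neutral_losses: Tuple[str, ...] = ()
    precursor_min: Optional[float] = None
    precursor_max: Optional[float] = None
    veto_losses: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(ion <= 0 for ion in self.marker_ions + self.companion_ions):
            raise ValueError(f"rule {self.rule_id}: non-positive marker ion")


_GALLOYL = (169.0137, 125.0243)

#: Default rule catalog, ordered by priority (chebuloyl > HHDP > galloyl;
#: within galloyl, glycosylated before free acids).
DEFAULT_RULES: Tuple[DiagnosticRule, ...] = (
    DiagnosticRule("chebuloyl-core", "chebulic ellagitannin", 10,
                   marker_ions=(337.0201, 319.0090, 293.0303)),
    DiagnosticRule("chebuloyl-cascade", "chebulic ellagitannin", 20,
                   marker_ions=(275.0200,), companion_ions=(205.0506,),
                   companion_required=1),
    DiagnosticRule("methyl-chebulate", "chebulic ellagitannin", 30,
                   marker_ions=(351.0345, 365.0502)),
    DiagnosticRule("chebulanin-family", "chebulic ellagitannin", 40,
                   marker_ions=(203.0344, 337.0560, 409.0770), required_count=2),
    DiagnosticRule("chebulanin-derivative", "chebulic ellagitannin", 50,
                   marker_ions=(435.0556,)),
    DiagnosticRule("chebulate-glycoside", "chebulic ellagitannin", 60,
                   marker_ions=(205.0506, 193.0141, 249.0401, 231.0290),
                   required_count=2, precursor_min=450.0),
    DiagnosticRule("hhdp-ellagic", "ellagitannin", 70,
                   marker_ions=(300.9990, 450.9940, 481.0663)),
    DiagnosticRule("dehydro-ellagic", "ellagitannin", 80,
                   marker_ions=(298.9832, 270.9880)),
    DiagnosticRule("galloyl-shikimate", "phenolcarboxylic acid", 90,
                   marker_ions=(93.0344,), companion_ions=_GALLOYL,
                   companion_required=1),
    DiagnosticRule("gallotannin-loss", "gallotannin", 100,
                   marker_ions=_GALLOYL,
                   neutral_losses=("gallate addition", "galloylation",
                                   "ketene loss", "hexosylation",
                                   "hexitol residue")),
    DiagnosticRule("gallotannin-glucose-ions", "gallotannin", 110,
                   marker_ions=_GALLOYL,
                   companion_ions=(313.0565, 271.0459, 211.0243),
                   companion_required=1),
    DiagnosticRule("gallate-ester", "phenolcarboxylic acid", 120,
                   marker_ions=(124.0166,), precursor_max=450.0),
    DiagnosticRule("free-galloyl-acid", "phenolcarboxylic acid", 130,
                   marker_ions=_GALLOYL, precursor_max=550.0,
                   veto_losses=("hexosylation",)),
    DiagnosticRule("free-chebulate", "phenolcarboxylic acid", 140,
                   marker_ions=(193.0141, 205.0506, 163.0398, 149.0244,
                                135.0452, 151.0398, 133.0656, 177.0551),
                   required_count=2, precursor_max=450.0),
    DiagnosticRule("urolithin-brevifolin", "phenolcarboxylic acid", 150,
                   marker_ions=(145.0293,), precursor_max=450.0),
)

#: Losses referenced by the rules but not part of the homolog catalog
#: defaults (a reduced-hexose residue, seen for galloyl hexitols).
_RULE_EXTRA_DELTAS: Tuple[MassDelta, ...] = (
    MassDelta("hexitol residue", 164.06847, 1),
)


def _loss_catalog(catalog: Sequence[MassDelta]) -> Dict[str, float]:
    table = {entry.name: entry.delta_mass for entry in catalog}
    for entry in _RULE_EXTRA_DELTAS:
        table.setdefault(entry.name, entry.delta_mass)
    return table


def _count_matches(targets: Sequence[float], fragments: Sequence[float], tol: float) -> int:
    return sum(
        1 for target in targets
        if any(abs(target - frag) <= tol for frag in fragments)
    )


def _loss_matches(
    loss_names: Sequence[str],
    precursor: float,
    fragments: Sequence[float],
    tol: float,
    losses: Dict[str, float],
) -> bool:
    for name in loss_names:
        try:
            delta = abs(losses[name])
        except KeyError:
            raise KeyError(f"neutral loss {name!r} not in mass-delta catalog")
        expected = precursor - delta
        if expected <= 0:
            continue
        if any(abs(expected - frag) <= tol for frag in fragments):
            return True
    return False


def rule_fires(
    rule: DiagnosticRule,
    precursor_mz: float,
    fragments: Sequence[float],
    tol: float,
    losses: Dict[str, float],
) -> bool:
    if rule.precursor_min is not None and precursor_mz < rule.precursor_min:
        return False
    if rule.precursor_max is not None and precursor_mz > rule.precursor_max:
        return False
    if rule.marker_ions and _count_matches(rule.marker_ions, fragments, tol) < rule.required_count:
        return False
    if rule.companion_required > 0:
        if _count_matches(rule.companion_ions, fragments, tol) < rule.companion_required:
            return False
    if rule.neutral_losses and not _loss_matches(
        rule.neutral_losses, precursor_mz, fragments, tol, losses
    ):
        return False
    if rule.veto_losses and _loss_matches(
        rule.veto_losses, precursor_mz, fragments, tol, losses
    ):
        return False
    return True


def classify_spectrum(
    precursor_mz: float,
    fragments: Sequence[float],
    rules: Sequence[DiagnosticRule] = DEFAULT_RULES,
    tol: float = 0.01,
    catalog: Sequence[MassDelta] = DEFAULT_MASS_DELTAS,
) -> Tuple[str, List[DiagnosticRule]]:
    """Assign a compound class by the highest-priority firing rule.

    Returns ``(class, fired_rules)``: the class of the first rule in
    priority order whose conditions hold, plus every rule of that same class
    that fires (for evidence reporting).  No firing rule gives
    ``("unclassified", [])``.
    """
    if not rules:
        raise ValueError("empty rule set")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    losses = _loss_catalog(catalog)
    ordered = sorted(rules, key=lambda r: (r.priority, r.rule_id))
    fired = [r for r in ordered if rule_fires(r, precursor_mz, fragments, tol, losses)]
    if not fired:
        return UNCLASSIFIED, []
    winning_class = fired[0].implied_class
    return winning_class, [r for r in fired if r.implied_class == winning_class]


def classify_msms(
    spectrum: MsmsSpectrum,
    rules: Sequence[DiagnosticRule] = DEFAULT_RULES,
    tol: float = 0.01,
) -> Tuple[str, List[DiagnosticRule]]:
    return classify_spectrum(spectrum.precursor_mz, list(spectrum.mz), rules, tol)


# ---------------------------------------------------------------------------
# Rule serialization
# ---------------------------------------------------------------------------

def save_rules(rules: Sequence[DiagnosticRule], path: str) -> None:
    with open(path, "w") as handle:
        json.dump([asdict(rule) for rule in rules], handle, indent=2)


def load_rules(path: str) -> List[DiagnosticRule]:
    with open(path) as handle:
        raw = json.load(handle)
    rules = []
    for item in raw:
        rules.append(DiagnosticRule(
            rule_id=item["rule_id"],
            implied_class=item["implied_class"],
            priority=int(item["priority"]),
            marker_ions=tuple(item.get("marker_ions", ())),
            required_count=int(item.get("required_count", 1)),
            companion_ions=tuple(item.get("companion_ions", ())),
            companion_required=int(item.get("companion_required", 0)),
            neutral_losses=tuple(item.get("neutral_losses", ())),
            precursor_min=item.get("precursor_min"),
            precursor_max=item.get("precursor_max"),
            veto_losses=tuple(item.get("veto_losses", ())),
        ))
    return rules


# ---------------------------------------------------------------------------
# Homologs and CCS
# ---------------------------------------------------------------------------

def infer_homolog(
    parent_mz: float,
    node_mz: float,
    catalog: Sequence[MassDelta] = DEFAULT_MASS_DELTAS,
    tol: float = 0.01,
) -> List[Tuple[MassDelta, int]]:
    """Explain ``node_mz − parent_mz`` as k-fold catalog modifications.

    E.g. chebulic acid [M−H]− 355.031 to the node at 369.047 is a +14.016
    difference: one methylation; to 411.093 (+56.062): four methylations.
    """
    if parent_mz <= 0 or node_mz <= 0:
        raise ValueError("m/z values must be positive")
    return annotate_mass_difference(node_mz - parent_mz, catalog, tol)


@dataclass(frozen=True)
class CcsComparison:
    """Measured vs predicted collision cross-section, in Å²."""

    measured: Optional[float]
    predicted: Optional[float]
    relative_deviation: Optional[float]
    status: str  # "match" | "flagged" | "not_evaluated"


def compare_ccs(
    measured: Optional[float],
    predicted: Optional[float],
    tol_percent: float = 3.0,
) -> CcsComparison:
    """Compare CCS values; deviation = |measured − predicted| / predicted × 100.

    Status "match" within ``tol_percent``, else "flagged".  A flagged
    comparison demotes a candidate in ranking but never removes it (CCS
    prediction is reliable for small galloyl glucoses and degrades for the
    large tannins).  Missing values give "not_evaluated".
    """
    if tol_percent <= 0:
        raise ValueError("tol_percent must be positive")
    if measured is None or predicted is None:
        return CcsComparison(measured, predicted, None, "not_evaluated")
    if measured <= 0 or predicted <= 0:
        raise ValueError("CCS values must be positive")
    deviation = abs(measured - predicted) / predicted * 100.0
    status = "match" if deviation <= tol_percent else "flagged"
    return CcsComparison(measured, predicted, deviation, status)


# ---------------------------------------------------------------------------
# Evidence integration
# ---------------------------------------------------------------------------

@dataclass
class AnnotationResult:
    """Merged identification evidence for one feature (one spectrum)."""

    spectrum_id: str
    precursor_mz: float
    rt: Optional[float]
    assigned_class: str
    candidates: List[LibraryHit] = field(default_factory=list)
    homolog_links: List[Tuple[int, str, int]] = field(default_factory=list)
    ccs_status: str = "not_evaluated"
    evidence_flags: Tuple[str, ...] = ()
    conflict: bool = False
    fired_rules: Tuple[str, ...] = ()

    @property
    def top_candidate(self) -> Optional[LibraryRecord]:
        return self.candidates[0].record if self.candidates else None


def _dedupe_candidates(hits: Sequence[LibraryHit]) -> List[LibraryHit]:
    seen = set()
    out = []
    for hit in hits:
        if hit.record.record_id not in seen:
            seen.add(hit.record.record_id)
            out.append(hit)
    return out


def integrate_evidence(
    spectrum_id: str,
    precursor_mz: float,
    rt: Optional[float],
    library_hits: Sequence[LibraryHit] = (),
    network_class: Optional[str] = None,
    rule_class: str = UNCLASSIFIED,
    fired_rules: Sequence[DiagnosticRule] = (),
    homologs: Sequence[Tuple[int, str, int]] = (),
    homolog_parent_class: Optional[str] = None,
    ccs: Optional[CcsComparison] = None,
) -> AnnotationResult:
    """Combine the evidence streams into one deterministic annotation.

    Precedence for the assigned class: standard-confirmed library hit >
    library hit consistent with the diagnostic class > diagnostic class
    (optionally homolog-supported) > network-propagated class.  Conflicting
    class evidence keeps the higher-precedence class and raises the
    ``conflict`` flag.  Candidates are de-duplicated by record id; a flagged
    CCS comparison demotes the affected top candidate below unflagged ones.
    """
    if not library_hits and network_class is None and rule_class == UNCLASSIFIED and not homologs:
        raise ValueError(f"feature {spectrum_id!r}: no evidence to integrate")

    candidates = _dedupe_candidates(library_hits)
    if ccs is not None and ccs.status == "flagged" and len(candidates) > 1:
        demoted = candidates[0]
        candidates = candidates[1:] + [demoted]

    flags: List[str] = []
    conflict = False
    assigned = UNCLASSIFIED

    standard_hits = [h for h in candidates if h.record.identified_by_standard]
    if standard_hits:
        assigned = standard_hits[0].record.compound_class
        flags.append("standard")
        flags.append("library")
        if rule_class != UNCLASSIFIED:
            flags.append("diagnostic")
            conflict = rule_class != assigned
    elif candidates and rule_class != UNCLASSIFIED:
        consistent = [h for h in candidates if h.record.compound_class == rule_class]
        if consistent:
            assigned = rule_class
            flags.extend(["library", "diagnostic"])
        else:
            assigned = candidates[0].record.compound_class
            flags.append("library")
            if rule_class != UNCLASSIFIED:
                flags.append("diagnostic")
                conflict = True
    elif candidates:
        assigned = candidates[0].record.compound_class
        flags.append("library")
    elif rule_class != UNCLASSIFIED:
        assigned = rule_class
        flags.append("diagnostic")
        if network_class not in (None, UNCLASSIFIED) and network_class != rule_class:
            conflict = True
    elif homologs and homolog_parent_class not in (None, UNCLASSIFIED):
        # homolog-only evidence: the feature inherits its parent's lineage
        assigned = homolog_parent_class
        flags.append("homolog")
    elif network_class not in (None, UNCLASSIFIED):
        assigned = network_class
        flags.append("network")

    if homologs:
        flags.append("homolog")
    if network_class not in (None, UNCLASSIFIED) and "network" not in flags:
        flags.append("network")
    if ccs is not None and ccs.status != "not_evaluated":
        flags.append("ccs")

    return AnnotationResult(
        spectrum_id=spectrum_id,
        precursor_mz=precursor_mz,
        rt=rt,
        assigned_class=assigned,
        candidates=candidates,
        homolog_links=list(homologs),
        ccs_status=ccs.status if ccs is not None else "not_evaluated",
        evidence_flags=tuple(dict.fromkeys(flags)),
        conflict=conflict,
        fired_rules=tuple(r.rule_id for r in fired_rules),
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def annotate_run(
    spectra: Sequence[MsmsSpectrum],
    library: Sequence[LibraryRecord],
    rules: Sequence[DiagnosticRule] = DEFAULT_RULES,
    params: NetworkParams = NetworkParams(),
    precursor_tol_ppm: float = 10.0,
    catalog: Sequence[MassDelta] = DEFAULT_MASS_DELTAS,
) -> Tuple[List[AnnotationResult], MolecularNetwork]:
    """Run the full identification pipeline over a set of MS/MS spectra.

    Networking → node annotation → component class labelling → per-spectrum
    diagnostic classification, homolog inference against annotated network
    neighbours, CCS comparison of the top candidate → evidence integration.
    Returns one :class:`AnnotationResult` per spectrum plus the network.
    """
    if not spectra:
        return [], MolecularNetwork(graph=nx.Graph(), params=params)

    network = build_network(spectra, params)
    annotate_nodes(network, library, spectra,
                   precursor_tol_ppm=precursor_tol_ppm,
                   fragment_tol=params.fragment_tol)
    component_classes = enhance_component_classes(network)
    record_by_id = {rec.record_id: rec for rec in library}

    results: List[AnnotationResult] = []
    for spec in sorted(spectra, key=lambda s: s.spectrum_id):
        node = network.graph.nodes[spec.spectrum_id]
        rule_class, fired = classify_msms(spec, rules, tol=params.fragment_tol)

        hits = search_precursor(spec.precursor_mz, library, tol_ppm=precursor_tol_ppm)
        if hits:
            hits = search_fragments(
                list(spec.mz), [h.record for h in hits],
                tol=params.fragment_tol, min_shared=0,
                precursor_mz=spec.precursor_mz,
            )

        network_class = node.get("component_class")
        if network_class == UNCLASSIFIED:
            network_class = None

        homologs: List[Tuple[int, str, int]] = []
        for neighbour in network.graph.neighbors(spec.spectrum_id):
            parent_id = network.graph.nodes[neighbour].get("annotation")
            if parent_id is None:
                continue
            parent_mz = network.graph.nodes[neighbour]["precursor_mz"]
            for delta, k in infer_homolog(parent_mz, spec.precursor_mz, catalog):
                homologs.append((parent_id, delta.name, k))

        ccs = None
        if hits:
            top = hits[0].record
            ccs = compare_ccs(top.measured_ccs, top.predicted_ccs)

        if not hits and network_class is None and rule_class == UNCLASSIFIED and not homologs:
            results.append(AnnotationResult(
                spectrum_id=spec.spectrum_id,
                precursor_mz=spec.precursor_mz,
                rt=spec.rt,
                assigned_class=UNCLASSIFIED,
            ))
            continue

        parent_class = None
        if homologs and homologs[0][0] in record_by_id:
            parent_class = record_by_id[homologs[0][0]].compound_class

        results.append(integrate_evidence(
            spec.spectrum_id, spec.precursor_mz, spec.rt,
            library_hits=hits,
            network_class=network_class,
            rule_class=rule_class,
            fired_rules=fired,
            homologs=homologs,
            homolog_parent_class=parent_class,
            ccs=ccs,
        ))
    return results, network


def class_count_summary(results: Sequence[AnnotationResult]) -> Dict[str, int]:
    """Count assigned classes across annotation results."""
    counts: Dict[str, int] = {}
    for res in results:
        counts[res.assigned_class] = counts.get(res.assigned_class, 0) + 1
    return counts


def write_annotations_tsv(results: Sequence[AnnotationResult], path: str) -> None:
    header = ["spectrum_id", "precursor_mz", "rt_min", "assigned_class",
              "top_candidate", "evidence", "ccs_status", "conflict"]
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for res in results:
            top = res.top_candidate
            handle.write("\t".join([
                res.spectrum_id,
                f"{res.precursor_mz:.4f}",
                "" if res.rt is None else f"{res.rt:.2f}",
                res.assigned_class,
                "" if top is None else f"{top.record_id}:{top.name}",
                ",".join(res.evidence_flags),
                res.ccs_status,
                str(int(res.conflict)),
            ]) + "\n")
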