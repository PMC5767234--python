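"""Producer assignment of induced features from 13C-labeling results.

An induced feature is attributed to the organism(s) whose post-induction
mono-culture incorporates tracer into it: labeled only in organism A ->
A_only, only in B -> B_only, in both -> both, in neither -> unassigned.
"Labeled" means a significant incorporation at any sampled timepoint of the
with-supernatant condition.  Unassigned features with a high co-culture
signal are flagged as physical-interaction candidates: their synthesis in
the co-culture evidently requires mycelial contact rather than diffusible
signals.  Features observed in both ionization modes are merged to
compound-level calls by shared formula and retention time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .labeling import LabelingResult

__all__ = [
    "ProducerCall",
    "assign_producer",
    "supernatant_dependence",
    "flag_physical_interaction",
    "deduplicate_features",
    "HIGH_SIGNAL_FLOOR",
]

#: co-culture intensity at or above which an unlabeled induced feature is
#: considered a physical-interaction candidate rather than a sensitivity miss
HIGH_SIGNAL_FLOOR = 1.0e4

CALL_ORDER = {"both": 3, "A_only": 2, "B_only": 2, "unassigned": 1}


@dataclass
class ProducerCall:
    """Producer attribution for one induced feature (or merged compound)."""

    feature_id: str
    call: str  # "A_only" | "B_only" | "both" | "unassigned"
    p_values: dict = field(default_factory=dict)
    incorporations: dict = field(default_factory=dict)
    supernatant_dependent: bool | None = None
    physical_interaction_candidate: bool = False
    merged_from: list[str] = field(default_factory=list)
    conflict_note: str | None = None


def _any_labeled(results: list[LabelingResult]) -> bool:
    return any(r.labeled for r in results)


def assign_producer(
    feature_id: str,
    results_a: list[LabelingResult],
    results_b: list[LabelingResult],
) -> ProducerCall:
    """Attribute a feature to organism A, B, both, or neither.

    ``results_a`` / ``results_b`` are the with-supernatant labeling results
    of the two mono-cultures at one or more timepoints; labeling at any
    timepoint counts (slow labelers may only reach significance late).
    """
    if not results_a or not results_b:
        raise ValueError("labeling results required for both organisms")
    lab_a, lab_b = _any_labeled(results_a), _any_labeled(results_b)
    call = {
        (True, False): "A_only",
        (False, True): "B_only",
        (True, True): "both",
        (False, False): "unassigned",
    }[(lab_a, lab_b)]
    pc = ProducerCall(feature_id=feature_id, call=call)
    for org, results in (("A", results_a), ("B", results_b)):
        for r in results:
            key = (org, r.timepoint)
            pc.p_values[key] = r.p_value
            pc.incorporations[key] = r.mean_incorporation
    return pc


def supernatant_dependence(
    with_sup: list[LabelingResult], without_sup: list[LabelingResult]
) -> bool | None:
    """Is labeling dependent on the co-culture supernatant?

    True when the feature is labeled with the supernatant but not without it
    (diffusible-signal induction); False when labeled in both conditions
    (constitutive); None when unlabeled in both (not evaluable).
    """
    if not with_sup or not without_sup:
        return None
    w, wo = _any_labeled(with_sup), _any_labeled(without_sup)
    if not w:
        return None
    return not wo


def flag_physical_interaction(
    co_mean_intensity: float,
    call: ProducerCall,
    high_signal_floor: float = HIGH_SIGNAL_FLOOR,
) -> bool:
    """Flag an unassigned induced feature with high co-culture signal.

    A feature that the co-culture produces abundantly yet neither separated
    mono-culture labels suggests synthesis requiring direct mycelial contact.
    Weak-signal unassigned features are not flagged (their missing label is
    attributed to sensitivity).
    """
    return call.call == "unassigned" and co_mean_intensity >= high_signal_floor


def deduplicate_features(
    calls: list[ProducerCall],
    targets: dict,
    rt_tol_min: float = 0.2,
) -> list[ProducerCall]:
    """Merge per-polarity feature calls into compound-level calls.

    ``targets`` maps feature id to an object with ``formula`` (Hill string or
    ElementalFormula), ``rt_min`` and ``polarity`` attributes (or a dict with
    those keys).  Features sharing a formula with RT within ``rt_tol_min``
    across opposite polarities merge; conflicting producer calls resolve to
    the more informative one (both > single organism > unassigned), with a
    note recorded.  A_only vs B_only conflicts resolve to both.
    """

    def meta(fid):
        t = targets[fid]
        if isinstance(t, dict):
            return str(t["formula"]), float(t["rt_min"]), t["polarity"]
        return str(t.formula), float(t.rt_min), t.polarity

    merged: list[ProducerCall] = []
    used: set[int] = set()
    for i, a in enumerate(calls):
        if i in used:
            continue
        group = [a]
        used.add(i)
        if a.feature_id in targets:
            fa, ra, pa = meta(a.feature_id)
            for j in range(i + 1, len(calls)):
                b = calls[j]
                if j in used or b.feature_id not in targets:
                    continue
                fb, rb, pb = meta(b.feature_id)
                if fb == fa and pb != pa and abs(rb - ra) <= rt_tol_min:
                    group.append(b)
                    used.add(j)
        if len(group) == 1:
            merged.append(a)
            continue
        calls_in_group = {g.call for g in group}
        if calls_in_group == {"A_only", "B_only"} or "both" in calls_in_group:
            resolved = "both"
        elif "A_only" in calls_in_group:
            resolved = "A_only"
        elif "B_only" in calls_in_group:
            resolved = "B_only"
        else:
            resolved = "unassigned"
        out = ProducerCall(
            feature_id="+".join(g.feature_id for g in group),
            call=resolved,
            merged_from=[g.feature_id for g in group],
        )
        for g in group:
            out.p_values.update(g.p_values)
            out.incorporations.update(g.incorporations)
        deps = {g.supernatant_dependent for g in group} - {None}
        out.supernatant_dependent = deps.pop() if len(deps) == 1 else None
        out.physical_interaction_candidate = any(
            g.physical_interaction_candidate for g in group
        )
        if len(calls_in_group) > 1:
            out.conflict_note = f"conflicting calls {sorted(calls_in_group)} -> {resolved}"
        merged.append(out)
    return merged
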