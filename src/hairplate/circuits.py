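"""Connectivity summaries and the signed motor impact score.

The central quantity is the motor impact score of a sensory population
(a hair plate) onto a motor module: the sum of an input-normalized
monosynaptic weight

    w1 = syn(HP -> module) / total input synapses of the module

and a signed di-synaptic weight accumulated over premotor interneurons

    w2 = sum_p  sign(p) * [syn(HP -> p) / total input of p]
                        * [syn(p -> module) / total input of the module],

where sign(p) is +1 for cholinergic and -1 for GABAergic/glutamatergic
premotor neurons (inferred from hemilineage annotations upstream). The
module's total input counts synapses from every annotated neuron,
including fragments labeled "other". No synapse-count threshold is applied
inside the score itself; thresholding (an average of >= `min_avg` synapses
per upstream neuron) is used when building circuit diagrams, and can be
imposed on the score via ``apply_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._errors import UndefinedFractionError
from .io import CELL_CLASSES, NeuronRecord


class SynapseGraph:
    """Annotated directed synapse graph over NeuronRecords.

    Edges are (pre_id, post_id, n_synapses) with positive integer counts;
    every edge endpoint must resolve against the annotation set.
    """

    def __init__(self, edges: pd.DataFrame, annotations: Iterable[NeuronRecord]):
        self.neurons = {r.neuron_id: r for r in annotations}
        edges = edges[["pre_id", "post_id", "n_synapses"]].copy()
        if len(edges):
            if (edges["n_synapses"] <= 0).any():
                raise ValueError("synapse counts must be positive")
            unresolved = (set(edges["pre_id"]) | set(edges["post_id"])) - set(self.neurons)
            if unresolved:
                raise ValueError(
                    f"{len(unresolved)} edge endpoints missing from annotations, "
                    f"e.g. {sorted(unresolved)[:5]}"
                )
            edges = edges.groupby(["pre_id", "post_id"], as_index=False, sort=False)[
                "n_synapses"
            ].sum()
        self.edges = edges.reset_index(drop=True)
        self._in = self.edges.groupby("post_id")["n_synapses"].sum().to_dict()
        self._out = self.edges.groupby("pre_id")["n_synapses"].sum().to_dict()

    # -- lookups ---------------------------------------------------------
    def total_input(self, neuron_id: str) -> int:
        return int(self._in.get(neuron_id, 0))

    def total_output(self, neuron_id: str) -> int:
        return int(self._out.get(neuron_id, 0))

    def by_class(self, cell_class: str) -> list[str]:
        return [i for i, r in self.neurons.items() if r.cell_class == cell_class]

    def hair_plate_members(self, hair_plate: str) -> list[str]:
        return [i for i, r in self.neurons.items() if r.hair_plate == hair_plate]

    def hair_plates(self) -> list[str]:
        return sorted({r.hair_plate for r in self.neurons.values() if r.hair_plate})

    def module_members(self, module: int) -> list[str]:
        return [
            i for i, r in self.neurons.items()
            if r.cell_class == "motor" and r.motor_module == module
        ]

    def modules(self) -> list[int]:
        return sorted({
            r.motor_module for r in self.neurons.values()
            if r.motor_module is not None
        })

    def resolve(self, label) -> list[str]:
        """Resolve a source label: a hair-plate name, a cell class, a
        hemilineage, or an explicit iterable of neuron ids."""
        if not isinstance(label, str):
            return list(label)
        members = self.hair_plate_members(label)
        if members:
            return members
        if label in CELL_CLASSES:
            return self.by_class(label)
        members = [i for i, r in self.neurons.items() if r.hemilineage == label]
        if members:
            return members
        raise ValueError(f"source label {label!r} matches no neurons")

    def module_total_input(self, module: int) -> int:
        """Total synapses onto the module's motor neurons from every
        annotated neuron (including fragments labeled other)."""
        return sum(self.total_input(m) for m in self.module_members(module))

    def synapses_between(self, pre_ids, post_ids) -> int:
        pre_ids, post_ids = set(pre_ids), set(post_ids)
        sel = self.edges["pre_id"].isin(pre_ids) & self.edges["post_id"].isin(post_ids)
        return int(self.edges.loc[sel, "n_synapses"].sum())


@dataclass
class ImpactScore:
    hair_plate: str
    module: int
    w1: float
    w2: float
    n_premotor: int = 0
    n_zero_sign: int = 0
    n_skipped: int = 0

    @property
    def total(self) -> float:
        return self.w1 + self.w2


@dataclass
class TwoLayerCircuit:
    source: str
    n_source: int
    premotor_groups: pd.DataFrame   # hemilineage, n_cells, sign, syn_from_source
    module_edges: pd.DataFrame      # hemilineage, module, n_synapses, sign
    direct_edges: pd.DataFrame      # module, n_synapses (source -> module, thresholded)
    recurrent_edges: pd.DataFrame   # premotor neuron -> source, counts
    min_avg: float = 4.0


def filter_class_edges(
    graph: SynapseGraph,
    source: str | Iterable[str],
    min_avg: float = 4.0,
    group_targets: bool = False,
) -> pd.DataFrame:
    """Aggregate source-class output and keep targets passing the
    average-synapses-per-source-neuron threshold.

    A target is retained iff the summed synapses it receives from all
    members of the source class is >= ``min_avg * n_members`` (boundary
    inclusive). With ``group_targets`` the aggregation is over target
    groups (hair plate / hemilineage / motor module / cell class) instead
    of single neurons.
    """
    members = graph.resolve(source)
    if not members:
        raise ValueError(f"source class {source!r} has no member neurons")
    n = len(members)
    sub = graph.edges[graph.edges["pre_id"].isin(set(members))]

    def target_key(post_id: str) -> str:
        r = graph.neurons[post_id]
        if r.hair_plate:
            return r.hair_plate
        if r.cell_class == "motor" and r.motor_module is not None:
            return f"module_{r.motor_module}"
        if r.hemilineage:
            return r.hemilineage
        return r.cell_class

    if group_targets:
        keys = sub["post_id"].map(target_key)
        agg = sub.groupby(keys)["n_synapses"].sum().rename_axis("target").reset_index()
    else:
        agg = (
            sub.groupby("post_id")["n_synapses"].sum()
            .rename_axis("target").reset_index()
        )
    agg["threshold"] = min_avg * n
    agg["retained"] = agg["n_synapses"] >= agg["threshold"]
    return agg.sort_values("n_synapses", ascending=False).reset_index(drop=True)


def output_fractions_by_class(
    graph: SynapseGraph, source: str | Iterable[str]
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Per-source-neuron fraction of output synapses onto each cell class.

    Returns (per-neuron fractions, summary with mean and SD across source
    neurons, count of sources excluded for having zero output synapses).
    Fractions for one neuron sum to 1 over the five cell classes.
    """
    members = graph.resolve(source)
    rows, excluded = [], 0
    for nid in members:
        total = graph.total_output(nid)
        if total == 0:
            excluded += 1
            continue
        out = graph.edges[graph.edges["pre_id"] == nid]
        by_cls = out.groupby(out["post_id"].map(lambda p: graph.neurons[p].cell_class))[
            "n_synapses"
        ].sum()
        rows.append(
            {"neuron_id": nid, "total_output": total,
             **{c: by_cls.get(c, 0) / total for c in CELL_CLASSES}}
        )
    if excluded:
        import logging
        logging.getLogger("hairplate").warning(
            "output_fractions_by_class: %d source neurons with zero outputs excluded",
            excluded,
        )
    per = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "cell_class": CELL_CLASSES,
            "mean": [per[c].mean() if len(per) else np.nan for c in CELL_CLASSES],
            "sd": [per[c].std(ddof=1) if len(per) > 1 else np.nan for c in CELL_CLASSES],
        }
    )
    return per, summary, excluded


def module_input_fraction(
    graph: SynapseGraph, source: str | Iterable[str], module: int
) -> tuple[float, pd.DataFrame]:
    """Fraction of a motor module's total input provided by a source set.

    Denominator is the summed input synapses onto all motor neurons of the
    module from every annotated neuron. Also returns the per-source-neuron
    decomposition (for dispersion across e.g. the 8 axons of a hair plate).
    """
    members = graph.resolve(source)
    motor = graph.module_members(module)
    total = graph.module_total_input(module)
    if total == 0:
        raise UndefinedFractionError(f"motor module {module} receives zero input synapses")
    sub = graph.edges[
        graph.edges["pre_id"].isin(set(members)) & graph.edges["post_id"].isin(set(motor))
    ]
    per = (
        sub.groupby("pre_id")["n_synapses"].sum()
        .reindex(members, fill_value=0)
        .rename("n_synapses").rename_axis("neuron_id").reset_index()
    )
    per["fraction"] = per["n_synapses"] / total
    return float(per["fraction"].sum()), per


def motor_impact(
    graph: SynapseGraph,
    hair_plate: str | Iterable[str],
    module: int,
    presyn_norm: str = "input",
    apply_threshold: bool = False,
    min_avg: float = 4.0,
) -> ImpactScore:
    """Signed motor impact of a hair plate onto a motor module.

    ``presyn_norm`` selects the first factor of the di-synaptic term:
    "input" (default) normalizes the hair-plate-to-premotor count by the
    premotor neuron's total input synapses; "output" normalizes it by the
    hair plate's total output synapses. Premotor neurons with unknown
    neurotransmitter (sign 0) contribute nothing and are counted; premotor
    neurons with zero recorded input are skipped and counted.
    """
    if presyn_norm not in ("input", "output"):
        raise ValueError("presyn_norm must be 'input' or 'output'")
    members = graph.resolve(hair_plate)
    hp_name = hair_plate if isinstance(hair_plate, str) else ",".join(sorted(members))
    motor = set(graph.module_members(module))
    module_in = graph.module_total_input(module)
    if module_in == 0:
        raise UndefinedFractionError(f"motor module {module} receives zero input synapses")

    w1, _ = module_input_fraction(graph, members, module)

    member_set = set(members)
    hp_out = (
        graph.edges[graph.edges["pre_id"].isin(member_set)]
        .groupby("post_id")["n_synapses"].sum()
    )
    premotor = [
        p for p in hp_out.index if graph.neurons[p].cell_class == "premotor"
    ]
    if apply_threshold:
        premotor = [p for p in premotor if hp_out[p] >= min_avg * len(members)]
    hp_total_out = sum(graph.total_output(m) for m in members)

    w2 = 0.0
    n_zero_sign = n_skipped = n_used = 0
    for p in premotor:
        p_to_mod = graph.synapses_between([p], motor)
        if p_to_mod == 0:
            continue
        sign = graph.neurons[p].sign
        if sign == 0:
            n_zero_sign += 1
            continue
        if presyn_norm == "input":
            denom = graph.total_input(p)
        else:
            denom = hp_total_out
        if denom == 0:
            n_skipped += 1
            import logging
            logging.getLogger("hairplate").warning(
                "motor_impact: premotor %s has zero %s synapses; path skipped",
                p, presyn_norm,
            )
            continue
        w2 += sign * (hp_out[p] / denom) * (p_to_mod / module_in)
        n_used += 1
    return ImpactScore(
        hair_plate=hp_name, module=module, w1=w1, w2=w2,
        n_premotor=n_used, n_zero_sign=n_zero_sign, n_skipped=n_skipped,
    )


def impact_matrix(graph: SynapseGraph, hair_plates=None, modules=None, **kw) -> pd.DataFrame:
    """Long-format impact table: one row per (hair plate, module)."""
    hair_plates = hair_plates if hair_plates is not None else graph.hair_plates()
    modules = modules if modules is not None else graph.modules()
    rows = []
    for hp in hair_plates:
        for m in modules:
            s = motor_impact(graph, hp, m, **kw)
            rows.append(
                {"hair_plate": hp, "module": m, "w1": s.w1, "w2": s.w2, "total": s.total}
            )
    return pd.DataFrame(rows)


def build_two_layer_circuit(
    graph: SynapseGraph, source: str, min_avg: float = 4.0
) -> TwoLayerCircuit:
    """Feedforward sensory -> premotor-hemilineage -> motor-module diagram.

    Premotor neurons are retained if they receive an average of >=
    ``min_avg`` synapses per source neuron, then grouped by hemilineage
    (unknown hemilineages grouped under "unknown"); each group's edges onto
    motor modules are retained under the same average rule with the group
    size as n. Direct source->module edges use the same rule with the
    source size. Premotor synapses back onto the source axons are reported
    separately and excluded from the feedforward diagram.
    """
    members = graph.resolve(source)
    n_src = len(members)
    member_set = set(members)
    fce = filter_class_edges(graph, members, min_avg=min_avg)
    kept = fce[fce["retained"]]

    pm_rows = []
    for _, row in kept.iterrows():
        r = graph.neurons[row["target"]]
        if r.cell_class == "premotor":
            pm_rows.append(
                {"neuron_id": r.neuron_id,
                 "hemilineage": r.hemilineage or "unknown",
                 "sign": r.sign, "syn_from_source": int(row["n_synapses"])}
            )
    pm = pd.DataFrame(pm_rows, columns=["neuron_id", "hemilineage", "sign", "syn_from_source"])
    groups = (
        pm.groupby("hemilineage")
        .agg(n_cells=("neuron_id", "count"), sign=("sign", "first"),
             syn_from_source=("syn_from_source", "sum"))
        .reset_index()
        if len(pm) else
        pd.DataFrame(columns=["hemilineage", "n_cells", "sign", "syn_from_source"])
    )

    mod_rows = []
    for _, g in groups.iterrows():
        ids = pm.loc[pm["hemilineage"] == g["hemilineage"], "neuron_id"]
        for m in graph.modules():
            syn = graph.synapses_between(ids, graph.module_members(m))
            if syn >= min_avg * g["n_cells"] and syn > 0:
                mod_rows.append(
                    {"hemilineage": g["hemilineage"], "module": m,
                     "n_synapses": syn, "sign": int(g["sign"])}
                )
    module_edges = pd.DataFrame(mod_rows, columns=["hemilineage", "module", "n_synapses", "sign"])

    direct_rows = []
    for m in graph.modules():
        syn = graph.synapses_between(member_set, graph.module_members(m))
        if syn >= min_avg * n_src and syn > 0:
            direct_rows.append({"module": m, "n_synapses": syn})
    direct = pd.DataFrame(direct_rows, columns=["module", "n_synapses"])

    rec = graph.edges[
        graph.edges["post_id"].isin(member_set)
        & graph.edges["pre_id"].map(
            lambda p: graph.neurons[p].cell_class == "premotor"
        )
    ][["pre_id", "post_id", "n_synapses"]].reset_index(drop=True)

    return TwoLayerCircuit(
        source=source if isinstance(source, str) else "custom",
        n_source=n_src, premotor_groups=groups, module_edges=module_edges,
        direct_edges=direct, recurrent_edges=rec, min_avg=min_avg,
    )
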