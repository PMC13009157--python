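"""Independent oracles and random-instance builders used across tests.

The oracles deliberately avoid the package's own aggregation code: the
impact oracle enumerates signed 1- and 2-hop paths with plain dict
arithmetic; the Kuiper oracle evaluates both empirical CDFs at every
sample point with a double loop.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hairplate.io import NeuronRecord

SIGN = {"acetylcholine": 1, "GABA": -1, "glutamate": -1, "unknown": 0}


def brute_force_impact(edges: pd.DataFrame, annotations, hp_label: str, module: int):
    """Enumerate all signed length-1 and length-2 paths from the hair
    plate's sensory cells to the module's motor neurons, with the same
    input normalization at each hop."""
    ann = {r.neuron_id: r for r in annotations}
    syn: dict = {}
    in_tot: dict = {}
    for row in edges.itertuples():
        syn[(row.pre_id, row.post_id)] = syn.get((row.pre_id, row.post_id), 0) + row.n_synapses
        in_tot[row.post_id] = in_tot.get(row.post_id, 0) + row.n_synapses
    sources = [i for i, r in ann.items() if r.hair_plate == hp_label]
    motors = [
        i for i, r in ann.items()
        if r.cell_class == "motor" and r.motor_module == module
    ]
    module_in = sum(in_tot.get(m, 0) for m in motors)
    w1 = sum(syn.get((s, m), 0) for s in sources for m in motors) / module_in
    w2 = 0.0
    for p, rp in ann.items():
        if rp.cell_class != "premotor":
            continue
        sgn = SIGN[rp.neurotransmitter]
        if sgn == 0 or in_tot.get(p, 0) == 0:
            continue
        for s in sources:
            for m in motors:
                if (s, p) in syn and (p, m) in syn:
                    w2 += sgn * (syn[(s, p)] / in_tot[p]) * (syn[(p, m)] / module_in)
    return w1, w2, w1 + w2


def random_annotated_graph(rng: np.random.Generator, max_nodes: int = 30):
    """Random annotated graph with one hair plate, a signed premotor pool,
    two motor modules, and background fragments."""
    n_sens = rng.integers(2, 5)
    n_pre = rng.integers(2, 7)
    n_mot1 = rng.integers(1, 4)
    n_mot2 = rng.integers(1, 4)
    n_other = rng.integers(1, 4)
    ann = []
    sens = [f"s{i}" for i in range(n_sens)]
    ann += [NeuronRecord(s, "sensory", hair_plate="HPX") for s in sens]
    pres = [f"p{i}" for i in range(n_pre)]
    nts = ["acetylcholine", "GABA", "glutamate", "unknown"]
    for p in pres:
        ann.append(
            NeuronRecord(p, "premotor", hemilineage=str(rng.integers(1, 25)) + "A",
                         neurotransmitter=nts[rng.integers(0, 4)])
        )
    mots = [f"m1_{i}" for i in range(n_mot1)] + [f"m2_{i}" for i in range(n_mot2)]
    ann += [NeuronRecord(m, "motor", motor_module=1 if m.startswith("m1") else 2)
            for m in mots]
    others = [f"o{i}" for i in range(n_other)]
    ann += [NeuronRecord(o, "other") for o in others]

    rows = []
    for s in sens:
        for t in pres + mots + others:
            if rng.random() < 0.5:
                rows.append((s, t, int(rng.integers(1, 25))))
    for p in pres:
        for t in mots + pres + sens:
            if t != p and rng.random() < 0.4:
                rows.append((p, t, int(rng.integers(1, 25))))
    for o in others:
        for t in pres + mots:
            if rng.random() < 0.6:
                rows.append((o, t, int(rng.integers(1, 25))))
    # every motor neuron needs some input for the score to be defined
    for m in mots:
        rows.append((others[0], m, int(rng.integers(1, 10))))
    edges = pd.DataFrame(rows, columns=["pre_id", "post_id", "n_synapses"])
    edges = edges.groupby(["pre_id", "post_id"], as_index=False)["n_synapses"].sum()
    return edges, ann


def kuiper_bruteforce(x, y) -> float:
    """Double-loop ECDF evaluation of the two-sample Kuiper statistic."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pts = np.concatenate([x, y])
    dplus = dminus = 0.0
    for t in pts:
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        dplus = max(dplus, fx - fy)
        dminus = max(dminus, fy - fx)
    return dplus + dminus
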