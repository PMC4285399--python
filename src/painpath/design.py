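"""Experimental design generator for the 9-run thermal pain task.

Each subject receives nine runs.  Runs 1, 2, 4, 5, 6, 8, 9 are passive
experience runs; runs 3 and 7 are regulation runs (regulate-up / -down,
order counterbalanced across subjects).  Runs 1, 2, 4, 8, 9 together deliver
55 stimulations over temperature levels 1-5 (11 per level) with the
within-run ordered transition between every pair of levels occurring exactly
twice, and the five runs starting with five distinct levels (runs 2 and 8
always start with levels 4 and 2).  Runs 5 and 6 repeat the run-4 and run-8
sequences with every level shifted up one degree (levels 2-6).  Regulation
runs contain ten trials, two at each of levels 1-5, in an order shared by
both regulation runs.

The transition constraint is solved exactly: the 55 trials define a directed
multigraph on the 5 levels holding two copies of every ordered pair
(self-loops included; 50 edges, in- and out-degree 10 everywhere).  A random
Eulerian circuit is cut into five 10-edge trails; cutting points are rotated
until the five trail starts are five distinct levels.  Each level is then
visited exactly 10 (edge entries) + 1 (trail start) = 11 times, so the
11-per-level count is automatic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import TEMP_LEVELS_C

__all__ = ["generate_design", "PASSIVE_CB_RUNS", "REGULATION_RUNS"]

#: passive runs participating in the transition counterbalancing
PASSIVE_CB_RUNS = (1, 2, 4, 8, 9)
REGULATION_RUNS = (3, 7)
#: runs that replay runs 4 and 8 with levels shifted +1
SHIFTED_RUNS = {5: 4, 6: 8}

_LEVELS = (1, 2, 3, 4, 5)

TRIAL_COLUMNS = [
    "subject", "run", "run_type", "trial_index",
    "temp_level", "temp_c", "reg_code", "rating", "decision",
    "excluded", "vif",
]


def _random_euler_circuit(rng: np.random.Generator) -> list[int]:
    """Hierholzer's algorithm with randomized edge choice.

    Returns a node sequence of length 51 (closed circuit) over levels 1-5
    using each ordered pair, self-loops included, exactly twice.
    """
    # adjacency multiset: two copies of every target per source
    adj = {u: [v for v in _LEVELS for _ in range(2)] for u in _LEVELS}
    for u in adj:
        rng.shuffle(adj[u])
    start = int(rng.integers(1, 6))
    stack, circuit = [start], []
    while stack:
        u = stack[-1]
        if adj[u]:
            stack.append(adj[u].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return circuit  # length 51, circuit[0] == circuit[-1]


def _passive_sequences(rng: np.random.Generator, max_attempts: int = 500) -> dict[int, list[int]]:
    """Five 11-trial level sequences satisfying all counterbalancing rules.

    Returns {run: sequence}; raises RuntimeError if no admissible cut of a
    random Eulerian circuit is found within ``max_attempts`` circuits (which
    signals an internal bug — the constraints are feasible).
    """
    for _ in range(max_attempts):
        circuit = _random_euler_circuit(rng)
        nodes = circuit[:-1]  # 50 nodes; edge k is nodes[k] -> nodes[(k+1) % 50]
        offsets = list(rng.permutation(50))
        for r in offsets:
            starts = [nodes[(r + 10 * i) % 50] for i in range(5)]
            if len(set(starts)) == 5:
                rot = nodes[r:] + nodes[:r]
                rot.append(rot[0])
                trails = [rot[10 * i: 10 * i + 11] for i in range(5)]
                # runs 2 and 8 must start with levels 4 and 2
                by_start = {t[0]: t for t in trails}
                seqs = {2: by_start[4], 8: by_start[2]}
                rest = [by_start[s] for s in (1, 3, 5)]
                order = rng.permutation(3)
                for run, k in zip((1, 4, 9), order):
                    seqs[run] = rest[k]
                return seqs
    raise RuntimeError(
        "failed to construct counterbalanced passive sequences; "
        "this indicates an internal constraint error"
    )


def _regulation_sequence(rng: np.random.Generator) -> list[int]:
    seq = [lv for lv in _LEVELS for _ in range(2)]
    rng.shuffle(seq)
    return seq


def _rows_for_run(subject: int, run: int, run_type: str, levels: list[int]) -> list[dict]:
    reg = {"passive": 0, "regulate_up": 1, "regulate_down": -1}[run_type]
    return [
        {
            "subject": subject,
            "run": run,
            "run_type": run_type,
            "trial_index": i + 1,
            "temp_level": lv,
            "temp_c": TEMP_LEVELS_C[lv],
            "reg_code": reg,
            "rating": np.nan,
            "decision": np.nan,
            "excluded": False,
            "vif": np.nan,
        }
        for i, lv in enumerate(levels)
    ]


def generate_design(n_subjects: int, seed: int) -> pd.DataFrame:
    """Generate the full 9-run trial table for ``n_subjects`` subjects.

    Regulation-run order alternates across subjects: odd-numbered subjects
    get regulate-up in run 3, even-numbered subjects regulate-down first.
    Rating/decision columns are NaN placeholders until responses are
    simulated (or observed data are merged in).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for subject in range(1, n_subjects + 1):
        seqs = _passive_sequences(rng)
        for run in (5, 6):
            seqs[run] = [lv + 1 for lv in seqs[SHIFTED_RUNS[run]]]
        reg_seq = _regulation_sequence(rng)
        up_first = subject % 2 == 1
        reg_types = {
            3: "regulate_up" if up_first else "regulate_down",
            7: "regulate_down" if up_first else "regulate_up",
        }
        for run in range(1, 10):
            if run in REGULATION_RUNS:
                rows.extend(_rows_for_run(subject, run, reg_types[run], reg_seq))
            else:
                rows.extend(_rows_for_run(subject, run, "passive", seqs[run]))
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["excluded"] = df["excluded"].astype(bool)
    return df


def validate_design(design: pd.DataFrame) -> None:
    """Assert every printed design constraint; raises AssertionError if violated."""
    for subject, d in design.groupby("subject"):
        passive = d[d["run"].isin(PASSIVE_CB_RUNS)]
        assert len(passive) == 55, "55 counterbalanced passive trials expected"
        counts = passive["temp_level"].value_counts()
        assert sorted(counts.index) == list(_LEVELS) and (counts == 11).all()
        # within-run ordered transitions: each of the 25 pairs exactly twice
        trans: dict[tuple[int, int], int] = {}
        starts = []
        for run in PASSIVE_CB_RUNS:
            seq = d.loc[d["run"] == run, "temp_level"].tolist()
            starts.append(seq[0])
            for u, v in zip(seq[:-1], seq[1:]):
                trans[(u, v)] = trans.get((u, v), 0) + 1
        assert len(trans) == 25 and all(c == 2 for c in trans.values())
        assert len(set(starts)) == 5
        assert d.loc[d["run"] == 2, "temp_level"].iloc[0] == 4
        assert d.loc[d["run"] == 8, "temp_level"].iloc[0] == 2
        for run, src in SHIFTED_RUNS.items():
            shifted = d.loc[d["run"] == run, "temp_level"].to_numpy()
            source = d.loc[d["run"] == src, "temp_level"].to_numpy()
            assert (shifted == source + 1).all()
        r3 = d.loc[d["run"] == 3, "temp_level"].tolist()
        r7 = d.loc[d["run"] == 7, "temp_level"].tolist()
        assert r3 == r7 and len(r3) == 10
        assert sorted(r3) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
        types = set(d.loc[d["run"].isin(REGULATION_RUNS), "run_type"])
        assert types == {"regulate_up", "regulate_down"}
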