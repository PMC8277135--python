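"""CPT initialization from ranked parent influences, manual adjustment, and
random CPT generation for testing.

The initializer is a documented stand-in for interactive elicitation tools:
each parent gets a direction (+/-) and a magnitude weight (or, for nominal
parents, per-state score offsets); a weighted score per parent combination
places the mode of a discretized Gaussian kernel over the child's ordered
states.  Explicitly elicited rows always take precedence via `adjust_cpt`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .bn_core import CPT, ModelError, VariableSpec, PROB_TOL

logger = logging.getLogger(__name__)

__all__ = [
    "ParentInfluence",
    "InfluenceRanking",
    "AdjustmentRecord",
    "initialize_cpt",
    "adjust_cpt",
    "random_cpt",
    "read_ranking_file",
    "write_audit_log",
    "DEFAULT_SPREAD",
]

#: default kernel width (in child state-index units); wide enough that a
#: neutral score leaves >=3 of 5 states with mass >= 0.05
DEFAULT_SPREAD = 1.0


@dataclass(frozen=True)
class ParentInfluence:
    """Direction (+1 pushes the child toward higher states) and weight of one
    parent; nominal parents declare per-state offsets in [-0.5, 0.5] instead."""

    weight: float
    direction: int = 0
    offsets: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ModelError("influence weights must be >= 0")
        if self.offsets is None and self.direction not in (-1, 0, 1):
            raise ModelError("direction must be -1, 0 or +1")
        if self.offsets is not None:
            object.__setattr__(self, "offsets", dict(self.offsets))


@dataclass(frozen=True)
class InfluenceRanking:
    child: str
    influences: Mapping[str, ParentInfluence]
    baseline: tuple[float, ...] | None = None
    spread: float = DEFAULT_SPREAD

    def __post_init__(self) -> None:
        object.__setattr__(self, "influences", dict(self.influences))
        if self.baseline is not None:
            b = np.asarray(self.baseline, dtype=float)
            if (b < 0).any() or abs(b.sum() - 1.0) > PROB_TOL:
                raise ModelError(f"baseline for {self.child!r} is not a distribution")
            object.__setattr__(self, "baseline", tuple(float(x) for x in b))
        if self.spread <= 0:
            raise ModelError("spread must be positive")


@dataclass(frozen=True)
class AdjustmentRecord:
    row_key: tuple[str, ...]
    old: tuple[float, ...]
    new: tuple[float, ...]
    session: str = ""


def _rank01(index: int, cardinality: int) -> float:
    """Even map of ordinal state indices onto [0, 1]."""
    if cardinality == 1:
        return 0.5
    return index / (cardinality - 1)


def _kernel(center: float, k: int, spread: float) -> np.ndarray:
    idx = np.arange(k, dtype=float)
    w = np.exp(-0.5 * ((idx - center) / spread) ** 2)
    return w / w.sum()


def initialize_cpt(
    child_spec: VariableSpec,
    parent_specs: Sequence[VariableSpec],
    ranking: InfluenceRanking,
    spread: float | None = None,
) -> CPT:
    """Populate a CPT from ranked parent influences.

    For every parent combination a normalized score in [0, 1] (0.5 = neutral)
    is the weighted mean of per-parent contributions:
    ``direction * (rank01(state) - 0.5)`` for ordinal parents, the declared
    per-state offset for nominal ones.  The score places the center of a
    discretized Gaussian over child state indices.  If every weight is zero
    the baseline is used for all rows (error if none was declared).
    """
    spread = ranking.spread if spread is None else spread
    if spread <= 0:
        raise ModelError("spread must be positive")
    k = child_spec.cardinality
    cards = [p.cardinality for p in parent_specs]
    names = [p.name for p in parent_specs]
    for name in names:
        if name not in ranking.influences:
            raise ModelError(f"ranking for {ranking.child!r} lacks parent {name!r}")

    total_weight = sum(ranking.influences[n].weight for n in names)
    if total_weight == 0:
        if ranking.baseline is None:
            raise ModelError(
                f"all influence weights for {ranking.child!r} are zero and no baseline is declared"
            )
        base = np.asarray(ranking.baseline, dtype=float)
        table = np.broadcast_to(base, tuple(cards) + (k,)).copy()
        return CPT(child=child_spec.name, parents=tuple(names), table=table)

    table = np.zeros(tuple(cards) + (k,))
    for combo in itertools.product(*(range(c) for c in cards)):
        contrib = 0.0
        for pi, (name, spec) in enumerate(zip(names, parent_specs)):
            infl = ranking.influences[name]
            if infl.offsets is not None:
                state = spec.states[combo[pi]]
                if state not in infl.offsets:
                    raise ModelError(
                        f"nominal parent {name!r}: no score offset for state {state!r}"
                    )
                contrib += infl.weight * float(infl.offsets[state])
            else:
                contrib += infl.weight * infl.direction * (_rank01(combo[pi], spec.cardinality) - 0.5)
        score = 0.5 + contrib / total_weight  # neutral combinations sit at 0.5
        table[combo] = _kernel(score * (k - 1), k, spread)
    return CPT(child=child_spec.name, parents=tuple(names), table=table)


def adjust_cpt(
    cpt: CPT,
    overrides: Sequence[tuple[Sequence[str], Sequence[float]]],
    parent_specs: Sequence[VariableSpec],
    session: str = "",
) -> tuple[CPT, list[AdjustmentRecord]]:
    """Replace specific rows verbatim; every other row is untouched.

    Returns the adjusted CPT and an audit log of the changed rows.
    """
    if tuple(s.name for s in parent_specs) != cpt.parents:
        raise ModelError("parent_specs must match the CPT parents in order")
    table = cpt.table.copy()
    audit: list[AdjustmentRecord] = []
    for states, vector in overrides:
        states = tuple(states)
        if len(states) != len(cpt.parents):
            raise ModelError(f"override key {states!r} does not cover parents {cpt.parents}")
        combo = tuple(spec.state_index(s) for spec, s in zip(parent_specs, states))
        vec = np.asarray(vector, dtype=float)
        if vec.shape != table[combo].shape or (vec < 0).any() or abs(vec.sum() - 1.0) > PROB_TOL:
            raise ModelError(f"override for {states!r} is not a valid distribution: {vector!r}")
        audit.append(
            AdjustmentRecord(
                row_key=states,
                old=tuple(table[combo].tolist()),
                new=tuple(vec.tolist()),
                session=session,
            )
        )
        table[combo] = vec
    return CPT(child=cpt.child, parents=cpt.parents, table=table), audit


def random_cpt(
    child_spec: VariableSpec,
    parent_specs: Sequence[VariableSpec],
    seed: int | np.random.Generator,
    concentration: float = 1.0,
    monotone: bool = False,
) -> CPT:
    """Rows drawn from a symmetric Dirichlet; reproducible from the seed.

    With ``monotone`` the rows are rearranged so that parent combinations
    with a higher ordinal score receive first-order stochastically larger
    child distributions (columns of the cumulative-sum matrix sorted
    decreasingly along the score order).
    """
    if concentration <= 0:
        raise ModelError("concentration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = child_spec.cardinality
    cards = [p.cardinality for p in parent_specs]
    n_rows = int(np.prod(cards)) if cards else 1
    rows = rng.dirichlet([concentration] * k, size=n_rows)

    if monotone and cards:
        combos = list(itertools.product(*(range(c) for c in cards)))
        scores = [
            sum(_rank01(j, c) for j, c in zip(combo, cards)) for combo in combos
        ]
        order = np.argsort(scores, kind="stable")
        cum = np.cumsum(rows, axis=1)
        # sort each CDF column descending: lowest-score row gets the largest
        # CDF (stochastically smallest distribution); row-wise monotonicity
        # of the CDF survives column-wise sorting
        cum_sorted = -np.sort(-cum, axis=0)
        restored = np.empty_like(cum_sorted)
        restored[order] = cum_sorted
        rows = np.diff(restored, axis=1, prepend=0.0)
        rows = np.clip(rows, 0.0, None)
        rows /= rows.sum(axis=1, keepdims=True)

    table = rows.reshape(tuple(cards) + (k,))
    return CPT(child=child_spec.name, parents=tuple(p.name for p in parent_specs), table=table)


# ---------------------------------------------------------------------------
# ranking file and audit log I/O

def read_ranking_file(path: str | Path) -> dict[str, InfluenceRanking]:
    """Structured ranking file: per child a baseline, spread, and per-parent
    direction/weight or per-state offsets."""
    doc = yaml.safe_load(Path(path).read_text())
    out = {}
    for entry in doc.get("rankings", []):
        influences = {}
        for name, infl in entry.get("parents", {}).items():
            influences[name] = ParentInfluence(
                weight=float(infl.get("weight", 1.0)),
                direction=int(infl.get("direction", 0)),
                offsets=infl.get("offsets"),
            )
        out[entry["child"]] = InfluenceRanking(
            child=entry["child"],
            influences=influences,
            baseline=tuple(entry["baseline"]) if "baseline" in entry else None,
            spread=float(entry.get("spread", DEFAULT_SPREAD)),
        )
    return out


def write_audit_log(records: Sequence[AdjustmentRecord], path: str | Path) -> None:
    lines = ["row_key\told\tnew\tsession"]
    for r in records:
        lines.append(
            "|".join(r.row_key)
            + "\t" + ",".join(repr(x) for x in r.old)
            + "\t" + ",".join(repr(x) for x in r.new)
            + "\t" + r.session
        )
    Path(path).write_text("\n".join(lines) + "\n")
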