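"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the library's inference and grid machinery: the
posterior oracle enumerates every full joint assignment in pure Python, and
the mortality oracle is a literal 101x101 double loop.
"""

import itertools
import math


def enumerate_posterior(network, query, evidence=None, policy=None):
    """Posterior over `query` states by full enumeration of the joint."""
    evidence = dict(evidence or {})
    policy = dict(policy or {})
    names = list(network.variables)
    states_of = {n: list(network.specs[n].states) for n in names}
    query_states = states_of[query]
    totals = [0.0] * len(query_states)
    for combo in itertools.product(*(states_of[n] for n in names)):
        assign = dict(zip(names, combo))
        if any(assign[v] != s for v, s in evidence.items()):
            continue
        p = 1.0
        for n in names:
            spec = network.specs[n]
            si = states_of[n].index(assign[n])
            if spec.node_kind == "decision":
                if n in evidence:
                    continue  # evidence already enforced above; mass 1
                pol = policy[n]
                if isinstance(pol, str):
                    p *= 1.0 if assign[n] == pol else 0.0
                else:
                    p *= float(pol[si])
            else:
                cpt = network.cpts[n]
                idx = tuple(states_of[q].index(assign[q]) for q in cpt.parents) + (si,)
                p *= float(cpt.table[idx])
            if p == 0.0:
                break
        totals[query_states.index(assign[query])] += p
    z = sum(totals)
    if z <= 0:
        raise ZeroDivisionError("evidence has zero likelihood")
    return [t / z for t in totals]


def combine_mortality_oracle(direct, indirect):
    """Literal double loop over all 101x101 (direct, indirect) percent pairs."""
    out = [0.0] * 101
    for d in range(101):
        for i in range(101):
            t = d + i * (100 - d) / 100.0
            out[int(math.floor(t + 0.5))] += direct[d] * indirect[i]
    return out


def grid_to_class_oracle(grid, bounds=((0, 10), (11, 30), (31, 60), (61, 80), (81, 100))):
    out = [0.0] * len(bounds)
    for v in range(101):
        for k, (lo, hi) in enumerate(bounds):
            if lo <= v <= hi:
                out[k] += grid[v]
                break
    return out
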