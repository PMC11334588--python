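"""Brute-force oracle: exhaustive enumeration of ordered outcome sequences.

Independent of the convolution recursion in ``seqdta.boundaries``: every
possible ordered Bernoulli failure sequence of the full final group is
enumerated, the stage at which it first crosses a boundary is found by
walking cumulative prefix counts, and the sequence probabilities are summed.
Only feasible for tiny designs (n_G <= ~14).
"""

from __future__ import annotations

import itertools

from seqdta.boundaries import UNATTAINABLE, BoundarySet


def enumerate_stagewise(boundaries: BoundarySet, p: float):
    """Stagewise stopping probabilities by path enumeration.

    Returns (futility, efficacy, no_stop, expected_sample_size).
    """
    sizes = boundaries.stage_sizes
    n_total = sizes[-1]
    n_stages = len(sizes)
    fut = [0.0] * n_stages
    eff = [0.0] * n_stages
    no_stop = 0.0
    expected_n = 0.0
    for bits in itertools.product((0, 1), repeat=n_total):
        k = sum(bits)
        prob = (p**k) * ((1.0 - p) ** (n_total - k))
        stopped = False
        for g, n_g in enumerate(sizes):
            failures = sum(bits[:n_g])
            r = boundaries.futility_counts[g]
            if r is not UNATTAINABLE and failures >= int(r):
                fut[g] += prob
                expected_n += n_g * prob
                stopped = True
                break
            if boundaries.efficacy_counts is not None:
                a = boundaries.efficacy_counts[g]
                if a is not UNATTAINABLE and failures <= int(a):
                    eff[g] += prob
                    expected_n += n_g * prob
                    stopped = True
                    break
        if not stopped:
            no_stop += prob
            expected_n += n_total * prob
    return fut, eff, no_stop, expected_n
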