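"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own computational paths: the
genotype-probability oracle enumerates all parental-origin assignments of a
DH chromatid with Haldane transition probabilities, and the scan oracle
solves the disconnected model's normal equations on explicit full design
matrices.
"""

import itertools

import numpy as np


def haldane(d_cm: float) -> float:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def enumerate_expected_count(
    marker_pos: list[float], observed: list, query_cm: float
) -> float:
    """E[allele-A count at query | observed marker alleles] by enumeration.

    ``observed`` holds 'A', 'B' or None per marker.  All 2^(m+1) joint
    parental-origin assignments of (markers + query locus) are enumerated
    with chain probabilities 0.5 * prod(transitions) under Haldane mapping;
    the conditional expectation marginalizes unobserved loci.
    """
    loci = sorted(set(marker_pos) | {query_cm})
    qi = loci.index(query_cm)
    obs_at = {}
    for pos, o in zip(marker_pos, observed):
        if o is not None:
            obs_at[loci.index(pos)] = o
    num = den = 0.0
    for states in itertools.product("AB", repeat=len(loci)):
        if any(states[i] != o for i, o in obs_at.items()):
            continue
        p = 0.5
        for a, b, d in zip(states, states[1:], np.diff(loci)):
            r = haldane(d)
            p *= (1.0 - r) if a == b else r
        den += p
        if states[qi] == "A":
            num += p
    return 2.0 * num / den


def disconnected_lod(
    y: np.ndarray, fam: np.ndarray, xq: np.ndarray, cof: list[np.ndarray] | None = None
) -> float:
    """LOD of the disconnected model from explicit full design matrices.

    Builds Y = J M (+ X_c B_c) + X_q B_q with N x P blocks whose column p
    is masked to family p, solves both models by least squares and returns
    (N/2) log10(RSS0/RSS1).
    """
    n = y.size
    P = int(fam.max()) + 1
    J = np.zeros((n, P))
    J[np.arange(n), fam] = 1.0

    def masked_block(x):
        return J * x[:, None]

    base = [J] + [masked_block(c) for c in (cof or [])]
    X0 = np.hstack(base)
    X1 = np.hstack(base + [masked_block(xq)])
    rss0 = float(np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2))
    rss1 = float(np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2))
    return (n / 2.0) * np.log10(rss0 / rss1)
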