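"""Independent brute-force oracles shared by the test modules."""

import itertools

import numpy as np


def brute_force_chain(responses, prior, k):
    """Exhaustive enumeration over all candidate chains (Viterbi oracle)."""
    from spinevb.localization import _response_candidates

    cand = []
    for resp in responses:
        coords, values = _response_candidates(resp, k)
        pos = resp.origin + coords * resp.spacing
        total = values.sum()
        probs = values / total if total > 0 else np.full(len(values), 1 / len(values))
        logs = np.maximum(
            np.log(probs, where=probs > 0, out=np.full_like(probs, -np.inf)),
            -1e12,
        )
        cand.append((pos, logs))
    best = None
    best_score = -np.inf
    for combo in itertools.product(*[range(len(c[0])) for c in cand]):
        score = sum(cand[i][1][ci] for i, ci in enumerate(combo))
        for i in range(len(combo) - 1):
            delta = cand[i + 1][0][combo[i + 1]] - cand[i][0][combo[i]]
            score += prior.transition_logpdf(i, delta)
        if score > best_score:
            best_score = score
            best = combo
    return np.stack([cand[i][0][ci] for i, ci in enumerate(best)])
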