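"""Independent literal-formula oracle for the sMFE score.

Everything here is written with plain Python loops and ``math`` only — no
numpy, no pandas, and no imports from the package under test — so that
agreement with the pipeline is a genuine two-route check.
"""

import math


def minmax_fit(reference):
    """Per-gene (min, max) over reference columns.  reference: {gene: [values]}."""
    return {g: (min(v), max(v)) for g, v in reference.items()}


def minmax_apply(fit, gene, value):
    lo, hi = fit[gene]
    if hi == lo:
        return 0.0
    x = (value - lo) / (hi - lo)
    return min(1.0, max(0.0, x))


def pearson(xs, ys):
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    if sxx == 0.0 or syy == 0.0:
        return 0.0
    r = sxy / math.sqrt(sxx * syy)
    return max(-1.0, min(1.0, r))


def pop_sd(xs):
    n = len(xs)
    m = sum(xs) / n
    return math.sqrt(sum((x - m) ** 2 for x in xs) / n)


def transition_probs(cohort, center, neighbors):
    """p_i = |PCC(neighbor_i, center)| / (1 + sum_j |PCC(neighbor_j, center)|)."""
    pccs = [abs(pearson(cohort[nb], cohort[center])) for nb in neighbors]
    denom = 1.0 + sum(pccs)
    return [c / denom for c in pccs]


def mfe(xbar, probs):
    total = 0.0
    for p in probs:
        u = xbar * p
        if u > 0.0:
            total -= u * math.log(u)
    return total


def local_smfe(reference, case, center, neighbors, sd_on="raw", eq6_form="product"):
    """Step-by-step differential score for one center gene.

    reference: {gene: [n values]}; case: {gene: value}.
    """
    fit = minmax_fit(reference)
    ref_norm = {g: [minmax_apply(fit, g, x) for x in v] for g, v in reference.items()}
    mixed_norm = {g: ref_norm[g] + [minmax_apply(fit, g, case[g])] for g in reference}

    p_n = transition_probs(ref_norm, center, neighbors)
    p_n1 = transition_probs(mixed_norm, center, neighbors)
    xbar_n = sum(ref_norm[center]) / len(ref_norm[center])
    xbar_n1 = sum(mixed_norm[center]) / len(mixed_norm[center])
    mfe_n = mfe(xbar_n, p_n)
    mfe_n1 = mfe(xbar_n1, p_n1)

    if sd_on == "raw":
        sd_n = pop_sd(reference[center])
        sd_n1 = pop_sd(reference[center] + [case[center]])
    else:
        sd_n = pop_sd(ref_norm[center])
        sd_n1 = pop_sd(mixed_norm[center])

    if eq6_form == "product":
        diff = sd_n * mfe_n - sd_n1 * mfe_n1
    else:
        diff = sd_n * mfe_n - sd_n1 + mfe_n1
    return abs(diff) / math.log(len(neighbors))


def score_sample(reference, case, out_neighbors, fraction=0.05, sd_on="raw"):
    """Full per-sample scoring: local scores, global score, signaling genes.

    out_neighbors: {gene: sorted list of out-neighbors}.  Centers are genes
    with >= 2 out-neighbors.  Q = ceil(fraction * L); ties at the cutoff by
    descending score then ascending gene ID.
    """
    centers = sorted(g for g, nbs in out_neighbors.items() if len(nbs) >= 2)
    local = {c: local_smfe(reference, case, c, out_neighbors[c], sd_on=sd_on)
             for c in centers}
    q = math.ceil(fraction * len(centers))
    ranked = sorted(centers, key=lambda g: (-local[g], g))[:q]
    global_score = sum(local[g] for g in ranked) / q
    return local, global_score, ranked
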