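"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: they work from
raw (species, lake, country, area, category) tuples with explicit loops
and literal weight tables, so agreement with the pipeline is a genuine
cross-check rather than a tautology.
"""

import itertools

import numpy as np

# Literal weight table (independent of cpirank.iucn.DEFAULT_WEIGHTS).
WEIGHTS = {
    "ET": 7, "EXw": 6, "CR": 5, "DD": 5, "NE": 5, "EN": 4, "VU": 3, "NT": 2, "LC": 1,
}


def brute_force_cpi(triples, areas, categories, k=8.0):
    """Recompute SRR, RRw, Cwt and CPI from raw occurrence triples.

    Parameters
    ----------
    triples:
        iterable of (species, lake, country) occurrence tuples.
    areas:
        mapping (lake, country) -> surface area in km².
    categories:
        mapping species -> category code; missing species count as NE.

    Returns
    -------
    dict mapping (lake, country) -> dict with srr-per-species, rrw, cwt, cpi.
    """
    triples = {(s, l, c) for (s, l, c) in triples}  # distinct only
    countries = {c for (_, _, c) in triples}
    out = {}
    for country in countries:
        lakes = sorted({l for (_, l, c) in triples if c == country})
        wt = len(lakes)
        species_here = sorted({s for (s, _, c) in triples if c == country})
        srr = {}
        for sp in species_here:
            ws = sum(1 for l in lakes if (sp, l, country) in triples)
            srr[sp] = 1.0 - ws / wt
        for lake in lakes:
            members = sorted({s for (s, l, c) in triples if l == lake and c == country})
            rrw = sum(srr[s] for s in members)
            cwt = sum(WEIGHTS[categories.get(s, "NE")] for s in members)
            area = areas[(lake, country)]
            out[(lake, country)] = {
                "species": members,
                "srr": {s: srr[s] for s in members},
                "wt": wt,
                "rrw": rrw,
                "cwt": cwt,
                "cpi": cwt * rrw / (area * k),
            }
    return out


def pearson_by_hand(x, y):
    """Textbook Pearson r: covariance over the product of standard deviations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def permutation_rank_p(x, y, n_resamples, seed):
    """Monte-Carlo permutation p for the two-sided rank-sum comparison.

    Independent of the analytic machinery: midranks are recomputed with
    argsort averaging and the null is sampled by shuffling group labels.
    """
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    n1 = len(x)

    def midranks(values):
        order = np.argsort(values, kind="mergesort")
        ranks = np.empty(len(values), float)
        i = 0
        sorted_vals = values[order]
        while i < len(values):
            j = i
            while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    ranks = midranks(pooled)
    mu = n1 * (len(pooled) - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    observed = abs(ranks[:n1].sum() - offset - mu)
    hits = 0
    for _ in range(n_resamples):
        idx = rng.permutation(len(pooled))[:n1]
        u = ranks[idx].sum() - offset
        if abs(u - mu) >= observed - 1e-12:
            hits += 1
    return hits / n_resamples


def exhaustive_accumulation_mean(species_sets):
    """Mean accumulation curve over every ordering of the sites."""
    n = len(species_sets)
    totals = np.zeros(n)
    count = 0
    for order in itertools.permutations(range(n)):
        seen = set()
        for j, idx in enumerate(order):
            seen = seen | set(species_sets[idx])
            totals[j] += len(seen)
        count += 1
    return totals / count
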