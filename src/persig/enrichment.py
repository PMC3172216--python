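"""Hypergeometric over-representation of signature genes in gene-set
categories.

For a universe of N genes containing K members of a category, and a
signature of n universe genes of which k fall in the category, the
over-representation p-value is the upper tail

    p = P(X >= k) = sum_{j=k}^{min(K,n)} C(K,j) C(N-K,n-j) / C(N,n).

One-sided over-representation only; BH q-values are reported across the
tested sets and the default significance cutoff is an unadjusted p < 0.001.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GeneSetCollection, GeneSignature, InputError
from .differential import bh_adjust


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Evaluated through the survival function of the hypergeometric
    distribution (computed from log-gamma terms, stable for large margins);
    exact to floating precision for small N.
    """
    for name, val in (("N", N), ("K", K), ("n", n), ("k", k)):
        if not float(val).is_integer() or val < 0:
            raise InputError(f"{name} must be a non-negative integer (got {val})")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N:
        raise InputError(f"margins exceed universe: K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise InputError(f"overlap k={k} exceeds min(K={K}, n={n})")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def enrich(
    signature: GeneSignature,
    sets: GeneSetCollection,
    universe: list[str] | set[str],
    p_cutoff: float = 0.001,
) -> pd.DataFrame:
    """Test every gene set for over-representation of signature genes.

    The signature is intersected with the universe before testing; one row
    per set with at least one universe member, sorted by p (ties by name),
    with BH q across tested sets and a significance flag at ``p_cutoff``.
    """
    universe = {str(g).upper() for g in universe}
    if not universe:
        raise InputError("universe is empty")
    sig_genes = {str(g).upper() for g in signature.genes} & universe
    if not sig_genes:
        raise InputError("signature has no genes in the universe")
    N = len(universe)
    n = len(sig_genes)
    rows = []
    for name, members in sets:
        members_in = {m for m in members} & universe
        K = len(members_in)
        if K == 0:
            continue
        overlap = sorted(members_in & sig_genes)
        k = len(overlap)
        p = hypergeom_upper_tail(N, K, n, k)
        rows.append(
            {
                "set_name": name,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p": p,
                "overlap_genes": overlap,
            }
        )
    if not rows:
        raise InputError("no gene set has members in the universe")
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["p"] < p_cutoff
    result = result.sort_values(
        ["p", "set_name"], kind="stable", ignore_index=True
    )
    return result[
        ["set_name", "N", "K", "n", "k", "p", "q", "significant", "overlap_genes"]
    ]


def enrichment_count_matrix(
    signatures: list[GeneSignature],
    sets: GeneSetCollection,
    universe: list[str] | set[str],
) -> pd.DataFrame:
    """Per-set overlap counts for several signatures side by side.

    Reproduces the category × time-point count layout used to compare
    early and late signatures; the final row holds each signature's size
    within the universe.
    """
    cols = {}
    for sig in signatures:
        res = enrich(sig, sets, universe, p_cutoff=1.0)
        cols[sig.name] = res.set_index("set_name")["k"]
    counts = pd.DataFrame(cols).fillna(0).astype(int)
    uni = {str(g).upper() for g in universe}
    totals = {
        sig.name: len({str(g).upper() for g in sig.genes} & uni)
        for sig in signatures
    }
    counts.loc["total_signature_genes"] = pd.Series(totals)
    return counts
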