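"""Donor-by-recipient continent flows of naturalized economic plants.

A flow matrix entry (d, r) counts the naturalized economic taxa that
are native to continent d and naturalized on continent r.  A taxon
native to several continents contributes one unit per donor continent;
a taxon naturalized on several continents contributes to each of those
recipient columns.  The null model keeps each recipient's taxon count
fixed and redraws which economic taxa arrived there, so only the donor
composition varies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CONTINENTS, TaxonTable, ValidationError
from .resampling import ResamplingResult, summarize_null

__all__ = ["observed_flows", "flow_null_test", "recipient_map_from_regions"]


def recipient_map_from_regions(region_set) -> dict[str, set]:
    """taxon_id -> set of continents where it is naturalized.

    Uses each region's ``continent`` attribute; regions without one are
    skipped.
    """
    out: dict[str, set] = {}
    for r in region_set:
        if r.continent is None:
            continue
        for tid in r.taxa:
            out.setdefault(tid, set()).add(r.continent)
    return out


def observed_flows(
    table: TaxonTable, recipient_map: dict
) -> tuple[pd.DataFrame, list[str]]:
    """Tabulate the donor-by-recipient flow matrix.

    Returns the 9x9 integer matrix (donor rows, recipient columns) and
    the list of naturalized economic taxa excluded for lacking native
    continents.
    """
    idx = {c: i for i, c in enumerate(CONTINENTS)}
    M = np.zeros((len(CONTINENTS), len(CONTINENTS)), dtype=np.int64)
    excluded: list[str] = []
    for t in table:
        if not (t.economic and t.naturalized):
            continue
        recips = recipient_map.get(t.taxon_id, set())
        if not recips:
            continue
        bad = [r for r in recips if r not in idx]
        if bad:
            raise ValidationError(
                f"taxon {t.taxon_id!r}: recipient continent(s) {bad} "
                "outside the TDWG alphabet"
            )
        if not t.native_continents:
            excluded.append(t.taxon_id)
            continue
        for r in recips:
            for d in t.native_continents:
                M[idx[d], idx[r]] += 1
    df = pd.DataFrame(M, index=list(CONTINENTS), columns=list(CONTINENTS))
    return df, sorted(excluded)


def flow_null_test(
    table: TaxonTable,
    recipient_map: dict,
    n_iter: int = 9999,
    seed: int = 0,
    return_null: bool = False,
):
    """Classify each flow cell against recipient-conditioned null draws.

    For each recipient continent r, every iteration draws (without
    replacement, from the pool of economic taxa with known native
    continents) as many taxa as were observed naturalized in r, and
    tabulates their donors.  The same taxon may be drawn for several
    recipients, mirroring that real taxa naturalize on several
    continents.
    """
    observed, _ = observed_flows(table, recipient_map)
    idx = {c: i for i, c in enumerate(CONTINENTS)}
    pool = [t for t in table if t.economic and t.native_continents]
    if not pool:
        raise ValidationError("no economic taxa with native continents")
    n_pool = len(pool)
    donor = np.zeros((n_pool, len(CONTINENTS)), dtype=np.int64)
    pool_ids = []
    for i, t in enumerate(pool):
        pool_ids.append(t.taxon_id)
        for d in t.native_continents:
            donor[i, idx[d]] = 1

    # observed number of naturalized economic taxa per recipient
    k_by_recipient = np.zeros(len(CONTINENTS), dtype=np.int64)
    econ_nat = {
        t.taxon_id
        for t in table
        if t.economic and t.naturalized and t.native_continents
    }
    for tid in econ_nat:
        for r in recipient_map.get(tid, set()):
            k_by_recipient[idx[r]] += 1

    rng = np.random.default_rng(seed)
    null = np.zeros((n_iter, len(CONTINENTS), len(CONTINENTS)), dtype=np.int64)
    for j, k_r in enumerate(k_by_recipient):
        k_r = int(k_r)
        if k_r == 0:
            continue
        if k_r > n_pool:
            raise ValidationError(
                f"recipient {CONTINENTS[j]}: {k_r} taxa exceeds pool {n_pool}"
            )
        chunk = max(1, min(n_iter, int(2e7 / max(n_pool, 1))))
        done = 0
        while done < n_iter:
            m = min(chunk, n_iter - done)
            keys = rng.random((m, n_pool))
            pick = np.argpartition(keys, k_r - 1, axis=1)[:, :k_r]
            null[done : done + m, :, j] = (
                donor[pick].sum(axis=1)
            )
            done += m

    results: dict[tuple[str, str], ResamplingResult] = {}
    for d in CONTINENTS:
        for r in CONTINENTS:
            obs = float(observed.loc[d, r])
            results[(d, r)] = summarize_null(
                obs, null[:, idx[d], idx[r]], seed
            )
    if return_null:
        return results, null
    return results


def flow_results_frame(results: dict) -> pd.DataFrame:
    """Long-format classification table for a flow_null_test result."""
    recs = []
    for (d, r), res in sorted(results.items()):
        recs.append(
            {
                "donor": d,
                "recipient": r,
                "observed": res.observed,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "p_two_sided": res.p_two_sided,
                "direction": res.direction,
            }
        )
    return pd.DataFrame.from_records(recs)
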