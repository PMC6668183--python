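"""Seed-and-merge differentially methylated region (DMR) calling, ordinal
dose/directional filtering, and DMC/DMR set comparisons.

A DMR is built around q-significant seed CpGs: a candidate region extends
``window`` bp up- and downstream of each seed (overlapping windows merged),
and within it maximal runs of consecutive tested CpGs that all have nominal
p below the threshold and the same direction of change are extracted.  Runs
with at least three members, at least one of which is a seed, are reported.
"Consecutive" means adjacent in the ordered list of tested CpGs: untested
CpGs cannot break a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DmrRecord",
    "call_dmrs",
    "dmrs_to_frame",
    "annotate_dmr_tss",
    "directional_filter",
    "compare_sets",
    "compare_dmr_sets",
]


@dataclass
class DmrRecord:
    """A merged region of consecutive same-direction significant CpGs."""

    chrom: str
    start: int                     # position of first member CpG (1-based)
    end: int                       # position of last member CpG (inclusive)
    member_pos: list[int]
    direction: str                 # 'hypo' | 'hyper'
    mean_q: float
    mean_methdiff: float
    n_seeds: int
    tss_distance: float = np.nan
    gene: str = ""

    @property
    def n_cpgs(self) -> int:
        return len(self.member_pos)


def _check_sorted(results: pd.DataFrame) -> None:
    seen = set()
    prev = None
    prev_pos = -1
    for c, p in zip(results["chrom"], results["pos"]):
        if c != prev:
            if c in seen:
                raise ValueError("results not sorted: chromosome split")
            seen.add(c)
            prev, prev_pos = c, p
        elif p <= prev_pos:
            raise ValueError(f"results not sorted at {c}:{p}")
        else:
            prev_pos = p


def call_dmrs(results: pd.DataFrame, q_threshold: float = 0.01,
              p_threshold: float = 0.01, window: int = 200) -> list[DmrRecord]:
    """Call DMRs from per-CpG association results (sorted by chrom, pos).

    Only converged tests participate.  Candidate regions are closed
    intervals [seed - window, seed + window] merged per chromosome; a CpG
    exactly on the boundary is inside.
    """
    _check_sorted(results)
    tested = results[results["converged"]
                     & np.isfinite(results["p_value"])].reset_index(drop=True)
    out: list[DmrRecord] = []
    for chrom, sub in tested.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        p = sub["p_value"].to_numpy()
        q = sub["q_value"].to_numpy()
        direction = np.sign(sub["beta"].to_numpy())
        methdiff = sub["methdiff"].to_numpy()

        seeds = np.isfinite(q) & (q < q_threshold)
        if not seeds.any():
            continue
        regions = _merge_windows(pos[seeds], window)
        qual = (p < p_threshold) & (direction != 0)
        for lo, hi in regions:
            a = int(np.searchsorted(pos, lo, side="left"))
            b = int(np.searchsorted(pos, hi, side="right"))
            out.extend(_emit_runs(chrom, pos[a:b], qual[a:b],
                                  direction[a:b], seeds[a:b],
                                  q[a:b], methdiff[a:b]))
    return out


def _merge_windows(seed_pos: np.ndarray, window: int) -> list[tuple[int, int]]:
    regions = []
    for s in seed_pos:
        lo, hi = int(s) - window, int(s) + window
        if regions and lo <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], hi)
        else:
            regions.append([lo, hi])
    return [tuple(r) for r in regions]


def _emit_runs(chrom, pos, qual, direction, seeds, q, methdiff):
    """Maximal runs of qualifying same-direction CpGs with >= 3 members and
    >= 1 seed."""
    out = []
    i, n = 0, len(pos)
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i + 1
        while j < n and qual[j] and direction[j] == direction[i]:
            j += 1
        n_seeds = int(seeds[i:j].sum())
        if j - i >= 3 and n_seeds >= 1:
            out.append(DmrRecord(
                chrom=chrom,
                start=int(pos[i]),
                end=int(pos[j - 1]),
                member_pos=[int(x) for x in pos[i:j]],
                direction="hyper" if direction[i] > 0 else "hypo",
                mean_q=float(np.mean(q[i:j])),
                mean_methdiff=float(np.mean(methdiff[i:j])),
                n_seeds=n_seeds,
            ))
        i = j
    return out


def dmrs_to_frame(dmrs: list[DmrRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": d.chrom, "start": d.start, "end": d.end,
        "n_cpgs": d.n_cpgs, "direction": d.direction,
        "mean_q": d.mean_q, "mean_methdiff": d.mean_methdiff,
        "n_seeds": d.n_seeds, "tss_distance": d.tss_distance,
        "gene": d.gene,
    } for d in dmrs],
        columns=["chrom", "start", "end", "n_cpgs", "direction", "mean_q",
                 "mean_methdiff", "n_seeds", "tss_distance", "gene"])


def annotate_dmr_tss(dmrs: list[DmrRecord], annotation) -> None:
    """Fill nearest-TSS distance (signed, strand-aware: negative = upstream
    of the gene) and gene label in place."""
    if "tss" not in annotation:
        return
    tss = annotation["tss"]
    by_chrom = {c: sub.reset_index(drop=True)
                for c, sub in tss.groupby("chrom", sort=False)}
    for d in dmrs:
        sub = by_chrom.get(d.chrom)
        if sub is None or len(sub) == 0:
            continue
        mid = (d.start + d.end) // 2
        tpos = sub["start"].to_numpy()
        k = int(np.argmin(np.abs(tpos - mid)))
        strand = sub["strand"].iloc[k] if "strand" in sub else "+"
        signed = (mid - tpos[k]) if strand == "+" else (tpos[k] - mid)
        d.tss_distance = float(signed)
        d.gene = str(sub["name"].iloc[k]) if "name" in sub else ""


# ---------------------------------------------------------------------------
# Dose/directional filtering
# ---------------------------------------------------------------------------

def directional_filter(m, samples: pd.DataFrame, dmcs: pd.DataFrame,
                       strict: bool = True, ra_strict: bool = False
                       ) -> pd.DataFrame:
    """Classify DMCs by monotone methylation change across ACPA levels.

    Group means are coverage-pooled ratios (sum meth / sum total over the
    group's unmasked samples).  Direction is ``hypo`` when the means
    strictly decrease across negative -> medium -> high, ``hyper`` when they
    strictly increase, else ``none``.  ``ra_consistent`` is true when the
    (non-``none``) trend extends through the RA group mean, with a weak
    inequality beyond the high group by default.
    """
    grp = samples["acpa_group"].to_numpy()
    ra = samples["ra"].to_numpy()
    masks = {
        "negative": (grp == "negative") & ~ra,
        "medium": (grp == "medium") & ~ra,
        "high": (grp == "high") & ~ra,
        "ra": ra,
    }
    for name, mask in masks.items():
        if not mask.any():
            raise ValueError(f"sample sheet has no samples in group {name!r}")

    keys = pd.MultiIndex.from_arrays([m.chrom, m.pos])
    want = pd.MultiIndex.from_arrays([dmcs["chrom"], dmcs["pos"]])
    locs = keys.get_indexer(want)
    if (locs < 0).any():
        raise ValueError("DMC not present in the methylation matrix")

    means = {}
    for name, mask in masks.items():
        tot = m.total[np.ix_(locs, np.flatnonzero(mask))].sum(axis=1).astype(float)
        me = m.meth[np.ix_(locs, np.flatnonzero(mask))].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            means[name] = np.where(tot > 0, me / tot, np.nan)

    lt = np.less if strict else np.less_equal
    inc = lt(means["negative"], means["medium"]) & lt(means["medium"], means["high"])
    dec = lt(means["medium"], means["negative"]) & lt(means["high"], means["medium"])
    direction = np.where(inc, "hyper", np.where(dec, "hypo", "none"))

    ra_cmp = np.less if ra_strict else np.less_equal
    ra_ok = np.where(
        direction == "hyper", ra_cmp(means["high"], means["ra"]),
        np.where(direction == "hypo", ra_cmp(means["ra"], means["high"]),
                 False))

    return pd.DataFrame({
        "chrom": dmcs["chrom"].to_numpy(),
        "pos": dmcs["pos"].to_numpy(),
        "mean_negative": means["negative"],
        "mean_medium": means["medium"],
        "mean_high": means["high"],
        "mean_ra": means["ra"],
        "direction": direction,
        "ra_consistent": ra_ok.astype(bool),
    })


# ---------------------------------------------------------------------------
# Set comparisons
# ---------------------------------------------------------------------------

def compare_sets(a, b) -> tuple[set, set, set, float]:
    """Exact partition of two identifier sets plus the Jaccard index."""
    a, b = set(a), set(b)
    shared = a & b
    union = a | b
    jaccard = len(shared) / len(union) if union else 1.0
    return shared, a - shared, b - shared, jaccard


def compare_dmr_sets(dmrs_a, dmrs_b) -> tuple[list, list, list, float]:
    """Compare two DMR lists by >= 1 bp interval intersection on the same
    chromosome.  Returns (shared index pairs, a-only, b-only, overlap
    fraction = matched intervals / all intervals)."""
    def _iv(d):
        return (d.chrom, d.start, d.end) if isinstance(d, DmrRecord) \
            else (d[0], d[1], d[2])

    a = [_iv(d) for d in dmrs_a]
    b = [_iv(d) for d in dmrs_b]
    shared = []
    hit_a, hit_b = set(), set()
    for i, (ca, sa, ea) in enumerate(a):
        for j, (cb, sb, eb) in enumerate(b):
            if ca == cb and sa <= eb and sb <= ea:
                shared.append((i, j))
                hit_a.add(i)
                hit_b.add(j)
    a_only = [i for i in range(len(a)) if i not in hit_a]
    b_only = [j for j in range(len(b)) if j not in hit_b]
    total = len(a) + len(b)
    frac = (len(hit_a) + len(hit_b)) / total if total else 1.0
    return shared, a_only, b_only, frac
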