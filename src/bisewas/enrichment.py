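"""Genomic-feature annotation, Fisher enrichment and discovery/validation
replication statistics.

CpGs are classified against interval tracks (CGI, gene model parts,
autoimmune-SNP windows).  The CGI-relative class follows the distance to
the nearest island edge: inside -> CGI; within 2 kb outside -> shore;
2-4 kb outside -> shelf; otherwise open sea.  Promoters are TSS1500 windows
(1500 bp upstream of a transcription start site, strand-aware, including
the TSS itself); an analogous 1500-bp downstream window flags transcription
end sites.  Enrichment is computed per CpG with a two-sided Fisher exact
test against a background of all testable CpGs; fold change below one
denotes depletion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

from .io_formats import FeatureAnnotation

__all__ = [
    "FEATURE_NAMES",
    "annotate_features",
    "feature_enrichment",
    "replicate",
    "replicate_dmrs",
]

FEATURE_NAMES = [
    "tss1500", "utr5", "first_exon", "exon", "intron", "utr3", "tes",
    "cgi", "cgi_shore", "cgi_shelf", "open_sea", "intergenic", "autoimmune",
]

SHORE_BP = 2000
SHELF_BP = 4000
TSS_WINDOW = 1500


def _interval_arrays(track: pd.DataFrame) -> dict[str, tuple]:
    """Per-chromosome merged sorted (starts, ends) arrays."""
    out = {}
    for chrom, sub in track.groupby("chrom", sort=False):
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        order = np.argsort(s, kind="mergesort")
        s, e = s[order], e[order]
        ms, me = [], []
        for a, b in zip(s, e):
            if ms and a <= me[-1] + 1:
                me[-1] = max(me[-1], b)
            else:
                ms.append(a)
                me.append(b)
        out[chrom] = (np.asarray(ms), np.asarray(me))
    return out


def _contains(ivals: dict, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    flags = np.zeros(len(pos), dtype=bool)
    for c in np.unique(chrom):
        if c not in ivals:
            continue
        s, e = ivals[c]
        sel = chrom == c
        p = pos[sel]
        k = np.searchsorted(s, p, side="right") - 1
        inside = (k >= 0) & (p <= e[np.clip(k, 0, len(e) - 1)])
        flags[sel] = inside
    return flags


def _edge_distance(ivals: dict, chrom: np.ndarray, pos: np.ndarray
                   ) -> np.ndarray:
    """Distance to the nearest interval edge; 0 inside, inf when the
    chromosome has no intervals."""
    dist = np.full(len(pos), np.inf)
    for c in np.unique(chrom):
        if c not in ivals:
            continue
        s, e = ivals[c]
        sel = chrom == c
        p = pos[sel]
        k = np.searchsorted(s, p, side="right") - 1
        kc = np.clip(k, 0, len(e) - 1)
        inside = (k >= 0) & (p <= e[kc])
        gap_left = np.where(k >= 0, p - e[kc], np.inf)
        nxt = np.clip(k + 1, 0, len(s) - 1)
        gap_right = np.where(k + 1 < len(s), s[nxt] - p, np.inf)
        d = np.where(inside, 0.0, np.minimum(gap_left, gap_right))
        dist[sel] = d
    return dist


def _strand_windows(track: pd.DataFrame, upstream: int, downstream: int
                    ) -> pd.DataFrame:
    """Strand-aware windows around point features (start == end)."""
    pos = track["start"].to_numpy(np.int64)
    strand = track["strand"].to_numpy() if "strand" in track \
        else np.full(len(track), "+")
    plus = strand == "+"
    start = np.where(plus, pos - upstream, pos - downstream)
    end = np.where(plus, pos + downstream, pos + upstream)
    return pd.DataFrame({"chrom": track["chrom"].to_numpy(),
                         "start": np.maximum(1, start), "end": end})


def annotate_features(cpgs: pd.DataFrame, ann: FeatureAnnotation
                      ) -> pd.DataFrame:
    """Flag every CpG (DataFrame with chrom, pos) against each feature.

    Flags are independent across tracks except for the mutually exclusive
    CGI/shore/shelf/open-sea partition.  CpGs on chromosomes missing from a
    track get all-False flags for it; a warning reports how many CpGs lay on
    chromosomes absent from every track.
    """
    chrom = cpgs["chrom"].to_numpy(dtype=object)
    pos = cpgs["pos"].to_numpy(np.int64)
    n = len(pos)
    out = pd.DataFrame({"chrom": chrom, "pos": pos})
    for f in FEATURE_NAMES:
        out[f] = False

    known_chroms = set()
    for df in ann.tracks.values():
        known_chroms.update(df["chrom"].unique())
    unknown = ~np.isin(chrom.astype(str), sorted(known_chroms))
    if unknown.any():
        warnings.warn(f"{int(unknown.sum())} CpGs lie on chromosomes absent "
                      "from the annotation; their flags are all False")

    if "cgi" in ann:
        cgi_iv = _interval_arrays(ann["cgi"])
        d = _edge_distance(cgi_iv, chrom, pos)
        out["cgi"] = d == 0
        out["cgi_shore"] = (d > 0) & (d <= SHORE_BP)
        out["cgi_shelf"] = (d > SHORE_BP) & (d <= SHELF_BP)
        out["open_sea"] = (d > SHELF_BP)
    else:
        out["open_sea"] = True
    out.loc[unknown, ["cgi", "cgi_shore", "cgi_shelf", "open_sea"]] = False

    tss_w = tes_w = None
    if "tss" in ann:
        tss_w = _interval_arrays(_strand_windows(ann["tss"], TSS_WINDOW, 0))
        out["tss1500"] = _contains(tss_w, chrom, pos)
    if "tes" in ann:
        tes_w = _interval_arrays(_strand_windows(ann["tes"], 0, TSS_WINDOW))
        out["tes"] = _contains(tes_w, chrom, pos)
    for track, feat in [("utr5", "utr5"), ("first_exon", "first_exon"),
                        ("exon", "exon"), ("intron", "intron"),
                        ("utr3", "utr3"), ("autoimmune", "autoimmune")]:
        if track in ann:
            out[feat] = _contains(_interval_arrays(ann[track]), chrom, pos)

    in_gene = _contains(_interval_arrays(ann["gene"]), chrom, pos) \
        if "gene" in ann else np.zeros(n, dtype=bool)
    out["intergenic"] = (~in_gene & ~out["tss1500"].to_numpy()
                         & ~out["tes"].to_numpy() & ~unknown)
    return out


def feature_enrichment(dmr_cpgs: pd.DataFrame, background_cpgs: pd.DataFrame,
                       ann: FeatureAnnotation,
                       features=None) -> pd.DataFrame:
    """Per-feature 2x2 Fisher enrichment of DMR CpGs vs all testable CpGs.

    Rows carry k (DMR CpGs in the feature), n (DMR CpGs), K (background in
    feature), N (background), fold change (k/n)/(K/N) and the two-sided
    Fisher p.  An empty feature yields fold NaN with p = 1.  No multiplicity
    correction is applied across features.
    """
    if len(dmr_cpgs) == 0:
        raise ValueError("empty DMR CpG set")
    bg_keys = set(zip(background_cpgs["chrom"], background_cpgs["pos"]))
    dm_keys = set(zip(dmr_cpgs["chrom"], dmr_cpgs["pos"]))
    if not dm_keys <= bg_keys:
        raise ValueError("DMR CpGs must be a subset of the background set")

    bg_flags = annotate_features(background_cpgs, ann)
    is_dmr = np.array([k in dm_keys
                       for k in zip(bg_flags["chrom"], bg_flags["pos"])])
    n = int(is_dmr.sum())
    N = len(bg_flags)
    rows = []
    for f in (features or FEATURE_NAMES):
        flag = bg_flags[f].to_numpy()
        k = int((flag & is_dmr).sum())
        K = int(flag.sum())
        if K == 0:
            rows.append((f, k, n, K, N, np.nan, 1.0))
            continue
        fold = (k / n) / (K / N)
        table = [[k, n - k], [K - k, (N - n) - (K - k)]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
        rows.append((f, k, n, K, N, fold, p))
    return pd.DataFrame(rows, columns=["feature", "k", "n", "K", "N",
                                       "fold_change", "p_value"])


# ---------------------------------------------------------------------------
# Discovery -> validation replication
# ---------------------------------------------------------------------------

def replicate(discovery: pd.DataFrame, validation: pd.DataFrame,
              disc_q: float = 0.01, val_p: float = 0.05) -> dict:
    """Replication of discovery DMCs in an independent validation cohort.

    Both inputs are per-CpG association tables.  The comparison is
    restricted to CpGs tested (converged) in both cohorts.  A discovery DMC
    (q < ``disc_q``) replicates when the validation p-value is below
    ``val_p`` with the same direction of change.  Fold enrichment compares
    the significance overlap with its expectation under independence;
    its p-value is an upper-tail hypergeometric.
    """
    d = discovery[discovery["converged"]]
    v = validation[validation["converged"]]
    merged = d.merge(v, on=["chrom", "pos"], suffixes=("_d", "_v"))
    n_common = len(merged)
    if n_common == 0:
        raise ValueError("no CpG tested in both cohorts")

    is_dmc = merged["q_value_d"] < disc_q
    val_sig = merged["p_value_v"] < val_p
    same_dir = merged["direction_d"] == merged["direction_v"]

    n_disc = int(is_dmc.sum())
    n_val = int(val_sig.sum())
    n_overlap = int((is_dmc & val_sig).sum())
    n_replicated = int((is_dmc & val_sig & same_dir).sum())

    if n_disc == 0:
        rate, fold, p = 0.0, np.nan, 1.0
    else:
        rate = n_replicated / n_disc
        expected = n_disc * n_val / n_common
        fold = n_overlap / expected if expected > 0 else np.nan
        p = float(hypergeom.sf(n_overlap - 1, n_common, n_val, n_disc))
    return {
        "n_common_tested": n_common,
        "n_discovery_dmcs_tested": n_disc,
        "n_validation_sig": n_val,
        "n_overlap": n_overlap,
        "n_replicated": n_replicated,
        "replication_rate": rate,
        "fold_enrichment": fold,
        "p_value": p,
    }


def replicate_dmrs(dmrs, validation: pd.DataFrame, val_p: float = 0.05
                   ) -> dict:
    """DMR-level replication: a discovery DMR replicates when at least one
    validation CpG inside its interval is nominally significant with the
    DMR's direction.  Only DMRs containing >= 1 tested validation CpG are
    considered 'also tested'."""
    v = validation[validation["converged"]]
    by_chrom = {c: sub.sort_values("pos").reset_index(drop=True)
                for c, sub in v.groupby("chrom", sort=False)}
    n_tested = 0
    n_rep = 0
    flags = []
    for d in dmrs:
        sub = by_chrom.get(d.chrom)
        if sub is None:
            flags.append(None)
            continue
        pos = sub["pos"].to_numpy()
        a = np.searchsorted(pos, d.start, side="left")
        b = np.searchsorted(pos, d.end, side="right")
        if b <= a:
            flags.append(None)
            continue
        n_tested += 1
        want = 1 if d.direction == "hyper" else -1
        block = sub.iloc[a:b]
        hit = bool(((block["p_value"] < val_p)
                    & (block["direction"] == want)).any())
        n_rep += hit
        flags.append(hit)
    return {
        "n_dmrs": len(dmrs),
        "n_also_tested": n_tested,
        "n_replicated": n_rep,
        "replication_rate": n_rep / n_tested if n_tested else np.nan,
        "flags": flags,
    }
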