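"""Locus rarefaction: node support as a function of the number of loci.

Random locus pools of increasing size (increments of five by default) are
drawn twenty times each; each draw is concatenated, bootstrapped, and
summarised by average internal-node support, tracked-clade supports, and the
number of nodes above the 50/70/90 % thresholds.  The curve answers the
question "would more loci keep improving resolution?" — a plateau says no.

Determinism: the subset drawn for (pool size, draw) depends only on the
master seed; the bootstrap seed is derived from the drawn subset itself, so
identical subsets (e.g. every draw at the full pool) give identical results
and the across-draw SD collapses to zero there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import stream, stream_seed
from .msa import Msa
from .supermatrix import concatenate
from .treesupport import (CladeDefinition, average_node_support,
                          bootstrap_support, clade_support, count_nodes_above)


@dataclass
class RarefactionConfig:
    increment: int = 5
    draws_per_size: int = 20
    thresholds: tuple = (50, 70, 90)
    bootstrap_replicates: int = 100
    codon_aware: bool = False
    master_seed: int = 0
    min_successful_draws_fraction: float = 0.5


@dataclass
class RarefactionCurve:
    results: pd.DataFrame      # one row per (pool_size, draw)
    summary: pd.DataFrame      # across-draw mean/SD per pool size
    clade_names: list = field(default_factory=list)
    seed: int = 0

    def mean_support_series(self) -> pd.Series:
        return self.summary.set_index("pool_size")["mean_support_mean"]


def subsample_loci(locus_ids: Sequence[str], pool_size: int, draw_index: int,
                   master_seed: int) -> list[str]:
    """Uniform sampling of loci without replacement, deterministic in
    (master_seed, pool_size, draw_index) and independent across draws."""
    ids = sorted(locus_ids)
    if pool_size > len(ids):
        raise ValueError(f"pool_size {pool_size} exceeds total loci {len(ids)}")
    rng = stream(master_seed, "subsample", pool_size, draw_index)
    chosen = rng.choice(len(ids), size=pool_size, replace=False)
    return [ids[i] for i in sorted(chosen)]


def pool_sizes(total: int, increment: int) -> list[int]:
    sizes = list(range(increment, total + 1, increment))
    if not sizes or sizes[-1] != total:
        sizes.append(total)
    return sizes


def run_rarefaction(curated_alignments: Mapping[str, Msa],
                    clades: Sequence[CladeDefinition] = (),
                    config: RarefactionConfig | None = None,
                    backend=None) -> RarefactionCurve:
    """The full rarefaction sweep over locus pool sizes.

    ``curated_alignments``: locus -> in-frame alignment over a shared taxon
    universe.  Draws whose tree inference fails are excluded (a pool size
    keeping fewer than half its draws is an error).  Results are cached per
    distinct locus subset, so repeated draws of the full pool cost one run.
    """
    cfg = config or RarefactionConfig()
    loci = sorted(curated_alignments)
    taxa = sorted({t for m in curated_alignments.values() for t in m.taxa})
    rows = []
    cache: dict[frozenset, dict] = {}
    for size in pool_sizes(len(loci), cfg.increment):
        ok_draws = 0
        for draw in range(cfg.draws_per_size):
            subset = subsample_loci(loci, size, draw, cfg.master_seed)
            key = frozenset(subset)
            if key not in cache:
                sm = concatenate({l: curated_alignments[l] for l in subset}, taxa)
                msa = sm.as_msa()
                boot_seed = stream_seed(cfg.master_seed, "boot", *sorted(subset))
                try:
                    st = bootstrap_support(msa, cfg.bootstrap_replicates,
                                           boot_seed, backend,
                                           codon_aware=cfg.codon_aware)
                    rec = {"mean_support": average_node_support(st)}
                    for thr in cfg.thresholds:
                        rec[f"n_gt{thr}"] = count_nodes_above(st, thr)
                    for clade in clades:
                        rec[f"clade_{clade.name}"] = clade_support(st, clade)
                    cache[key] = rec
                except Exception:
                    cache[key] = {}
            rec = cache[key]
            if not rec:
                continue
            ok_draws += 1
            rows.append({"pool_size": size, "draw": draw, **rec})
        if ok_draws < cfg.min_successful_draws_fraction * cfg.draws_per_size:
            raise RuntimeError(
                f"pool size {size}: only {ok_draws}/{cfg.draws_per_size} "
                "draws succeeded")
    results = pd.DataFrame(rows)
    value_cols = [c for c in results.columns if c not in ("pool_size", "draw")]
    agg = results.groupby("pool_size")[value_cols].agg(["mean", "std"])
    agg.columns = [f"{a}_{b}" for a, b in agg.columns]
    summary = agg.reset_index().fillna(0.0)
    return RarefactionCurve(results, summary,
                            [c.name for c in clades], cfg.master_seed)


def plateau_detect(series: "pd.Series | Sequence[float]", window: int = 3,
                   tolerance: float = 2.0,
                   sizes: Sequence[int] | None = None) -> int | None:
    """Smallest pool size after which the mean-support series stays flat.

    A candidate index i qualifies when every later value deviates by
    strictly less than ``tolerance`` support points from the running mean of
    the (up to ``window``) values preceding it, with the window confined to
    indices >= i.  A candidate must have at least one later value, so a
    series that climbs faster than the tolerance to its end never plateaus.
    Returns the pool size (or the index when sizes are unknown); None when
    the series never plateaus.
    """
    if isinstance(series, pd.Series):
        if sizes is None:
            sizes = list(series.index)
        values = series.to_numpy(dtype=float)
    else:
        values = np.asarray(list(series), dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 pool sizes")
    for i in range(n - 1):
        ok = True
        for j in range(i + 1, n):
            lo = max(i, j - window)
            if abs(values[j] - values[lo:j].mean()) >= tolerance:
                ok = False
                break
        if ok:
            return int(sizes[i]) if sizes is not None else i
    return None


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_curve(curve: RarefactionCurve, path: str | Path) -> None:
    """Tidy per-draw table (pool_size, draw, mean_support, clade columns,
    n_gt* counts)."""
    curve.results.to_csv(path, sep="\t", index=False)


def write_summary(curve: RarefactionCurve, path: str | Path) -> None:
    curve.summary.to_csv(path, sep="\t", index=False)


def plot_rarefaction(curve: RarefactionCurve, path: str | Path | None = None):
    """Mean-support and node-count curves with across-draw SD bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    s = curve.summary
    axes[0].errorbar(s["pool_size"], s["mean_support_mean"],
                     yerr=s["mean_support_std"], marker="o")
    axes[0].set_xlabel("loci in pool")
    axes[0].set_ylabel("average node support (%)")
    for col in s.columns:
        if col.startswith("n_gt") and col.endswith("_mean"):
            axes[1].plot(s["pool_size"], s[col], marker="o",
                         label=col.replace("_mean", ""))
    axes[1].set_xlabel("loci in pool")
    axes[1].set_ylabel("nodes above threshold")
    axes[1].legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
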