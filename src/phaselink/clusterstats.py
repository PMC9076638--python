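"""Nonparametric cluster-based inference for time-frequency maps.

Three-step scheme applied identically to ISPC and dB-power maps:

1. :func:`within_subject_z` -- permutation z-transform of the change from
   baseline within a subject: the observed TOI-minus-baseline ISPC
   difference is standardized against a null built by randomly exchanging
   each trial's time-of-interest and baseline phase contributions
   (1000 permutations by default). The result, zISPC, is an effect size of
   change from baseline per condition.
2. :func:`cluster_permutation` -- group-level inference: a two-tailed t map
   over subjects is thresholded at the cluster-forming alpha, contiguous
   supra-threshold cells (4-connectivity on the time x frequency grid) are
   aggregated into clusters, and each cluster's mass (sum of t; extent is
   available as an option) is referred to the permutation distribution of
   the maximum cluster mass under sign flips (one-sample) or group-label
   permutation (between groups). p_cluster uses the (b+1)/(m+1) rule.
3. :func:`contrast_maps` -- the transition-mode x age-group contrast
   scheme: per-subject (in-phase minus anti-phase) difference maps feed a
   between-group test of the interaction; main-effect inputs are provided
   for the follow-up tests run when the interaction is null.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
from scipy import ndimage, stats

from ._utils import keyed_rng

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Cluster:
    mass: float
    extent: int
    p_cluster: float
    freq_range: tuple
    time_range: tuple
    cells: np.ndarray  # (k, 2) array of (freq_idx, time_idx)


@dataclass
class ClusterResult:
    clusters: list
    t_map: np.ndarray
    threshold: float
    n_permutations: int
    alpha: float
    tail: str = "two"
    design: str = "one-sample"
    stat: str = "mass"
    seed: int | None = None
    null_max: np.ndarray | None = None

    def significant(self):
        return [c for c in self.clusters if c.p_cluster < self.alpha]

    def to_json(self, path) -> None:
        payload = {
            "design": self.design, "stat": self.stat, "alpha": self.alpha,
            "tail": self.tail, "n_permutations": self.n_permutations,
            "threshold": self.threshold, "seed": self.seed,
            "note": ("cluster statistic is mass (sum of t); set stat='extent' "
                     "for a count-of-cells statistic"),
            "clusters": [
                {"mass": c.mass, "extent": c.extent, "p": c.p_cluster,
                 "freq_range": list(c.freq_range),
                 "time_range": list(c.time_range),
                 "cells": c.cells.tolist()}
                for c in self.clusters
            ],
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=1)


# ---------------------------------------------------------------------------
# within-subject permutation z
# ---------------------------------------------------------------------------

def within_subject_z(dphi_toi: np.ndarray, dphi_base: np.ndarray,
                     n_perm: int = 1000, seed: int = 0,
                     chunk: int = 8) -> np.ndarray:
    """Permutation z-transform of ISPC change from baseline.

    ``dphi_toi`` is [trial, freq, time]: per-trial phase-angle differences
    in the time of interest. ``dphi_base`` is [trial, freq, time_b] over
    the baseline window; one baseline time point is drawn per trial to pair
    with that trial's TOI series. The null exchanges, per trial, the TOI
    and baseline assignment; z = (observed - null mean) / null SD. Cells
    with zero null SD come back NaN (masked).
    """
    toi = np.exp(1j * np.asarray(dphi_toi, dtype=float))
    base_all = np.exp(1j * np.asarray(dphi_base, dtype=float))
    n_tr = toi.shape[0]
    if n_tr < 2:
        raise ValueError("need >= 2 trials to permute")
    rng = keyed_rng(seed, "within_subject_z")
    pick = rng.integers(0, base_all.shape[2], size=n_tr)
    base = base_all[np.arange(n_tr), :, pick][:, :, None]  # [trial, freq, 1]

    obs = np.abs(toi.mean(axis=0)) - np.abs(np.broadcast_to(
        base, toi.shape).mean(axis=0))

    null = np.empty((n_perm,) + obs.shape)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        flips = rng.integers(0, 2, size=(m, n_tr)).astype(bool)
        f = flips[:, :, None, None]
        grp1 = np.where(f, base, toi[None]).mean(axis=1)
        grp2 = np.where(f, toi[None], np.broadcast_to(base, toi.shape)[None]
                        ).mean(axis=1)
        null[done:done + m] = np.abs(grp1) - np.abs(grp2)
        done += m
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mu) / sd
    z[sd == 0] = np.nan
    return z


# ---------------------------------------------------------------------------
# group-level cluster permutation
# ---------------------------------------------------------------------------

def _t_one_sample(maps: np.ndarray) -> np.ndarray:
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def _t_two_sample(maps: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    a, b = maps[is_a], maps[~is_a]
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp * (1 / na + 1 / nb))
    t[~np.isfinite(t)] = 0.0
    return t


def _cluster_stats(t: np.ndarray, thr: float, stat: str):
    """Cluster masses/extents and labels for both tails."""
    out = []
    for sign in (1.0, -1.0):
        mask = (sign * t) > thr
        labels, k = ndimage.label(mask, structure=FOUR_CONN)
        for lab in range(1, k + 1):
            cells = labels == lab
            mass = float(t[cells].sum())
            extent = int(cells.sum())
            out.append((mass, extent, np.argwhere(cells)))
    return out


def _max_cluster_stat(t: np.ndarray, thr: float, stat: str) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        labels, k = ndimage.label((sign * t) > thr, structure=FOUR_CONN)
        if k == 0:
            continue
        idx = np.arange(1, k + 1)
        if stat == "mass":
            vals = np.abs(ndimage.sum_labels(t, labels, idx))
        else:
            vals = ndimage.sum_labels(np.ones_like(t), labels, idx)
        best = max(best, float(vals.max()))
    return best


def cluster_permutation(maps: np.ndarray, design: str = "one-sample",
                        groups: np.ndarray | None = None,
                        n_perm: int = 1000, alpha: float = 0.05,
                        cluster_forming_p: float = 0.05,
                        stat: str = "mass", seed: int = 0,
                        freqs_hz: np.ndarray | None = None,
                        time_s: np.ndarray | None = None) -> ClusterResult:
    """Cluster-corrected permutation test on subject-level maps.

    ``maps`` is [subject, freq, time]. ``design`` is 'one-sample' (t against
    0, permutation by sign flip) or 'between-group' (two-sample t,
    permutation of the group allocation; ``groups`` gives the labels).
    """
    maps = np.asarray(maps, dtype=float)
    n_sub = maps.shape[0]
    if design not in ("one-sample", "between-group"):
        raise ValueError(f"unknown design {design!r}")
    if design == "between-group":
        if groups is None:
            raise ValueError("between-group design needs group labels")
        groups = np.asarray(groups)
        is_a = groups == np.unique(groups)[0]
        if min(is_a.sum(), (~is_a).sum()) < 4:
            raise ValueError("need >= 4 subjects per group")
        df = n_sub - 2
        t_obs = _t_two_sample(maps, is_a)
    else:
        if n_sub < 4:
            raise ValueError("need >= 4 subjects")
        df = n_sub - 1
        t_obs = _t_one_sample(maps)
    if n_perm < 100:
        import warnings
        warnings.warn(f"n_perm={n_perm} gives unstable p resolution",
                      stacklevel=2)
    thr = float(stats.t.ppf(1 - cluster_forming_p / 2, df))

    rng = keyed_rng(seed, "cluster_permutation")
    shape_ft = maps.shape[1:]
    flat = maps.reshape(n_sub, -1)
    null = np.empty(n_perm)
    batch = 64
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        if design == "one-sample":
            flips = rng.choice([-1.0, 1.0], size=(m, n_sub))
            s1 = flips @ flat  # sum of flipped maps
            mean = s1 / n_sub
            sumsq = (flat ** 2).sum(axis=0)  # invariant to sign flips
            var = (sumsq - n_sub * mean ** 2) / (n_sub - 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_batch = mean / np.sqrt(var / n_sub)
        else:
            na = int(is_a.sum())
            sel = np.stack([rng.permutation(is_a) for _ in range(m)]
                           ).astype(float)
            sa = sel @ flat
            sb = flat.sum(axis=0) - sa
            sa2 = sel @ flat ** 2
            sb2 = (flat ** 2).sum(axis=0) - sa2
            nb = n_sub - na
            ma_, mb_ = sa / na, sb / nb
            va = (sa2 - na * ma_ ** 2) / (na - 1)
            vb = (sb2 - nb * mb_ ** 2) / (nb - 1)
            sp = ((na - 1) * va + (nb - 1) * vb) / (n_sub - 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_batch = (ma_ - mb_) / np.sqrt(sp * (1 / na + 1 / nb))
        t_batch = np.nan_to_num(t_batch, nan=0.0, posinf=0.0, neginf=0.0)
        for j in range(m):
            null[done + j] = _max_cluster_stat(
                t_batch[j].reshape(shape_ft), thr, stat)
        done += m

    clusters = []
    for mass, extent, cells in _cluster_stats(t_obs, thr, stat):
        val = abs(mass) if stat == "mass" else float(extent)
        p_c = (np.sum(null >= val) + 1.0) / (n_perm + 1.0)
        fidx, tidx = cells[:, 0], cells[:, 1]
        fr = ((freqs_hz[fidx].min(), freqs_hz[fidx].max())
              if freqs_hz is not None else (int(fidx.min()), int(fidx.max())))
        tr = ((time_s[tidx].min(), time_s[tidx].max())
              if time_s is not None else (int(tidx.min()), int(tidx.max())))
        clusters.append(Cluster(mass=mass, extent=extent, p_cluster=float(p_c),
                                freq_range=fr, time_range=tr, cells=cells))
    clusters.sort(key=lambda c: c.p_cluster)
    return ClusterResult(clusters=clusters, t_map=t_obs, threshold=thr,
                         n_permutations=n_perm, alpha=alpha, design=design,
                         stat=stat, seed=seed, null_max=null)


def contrast_maps(z_maps: dict, groups: dict):
    """Build the contrast inputs of the group x transition-mode scheme.

    ``z_maps`` maps subject -> {"into_IP": map, "into_AP": map}; ``groups``
    maps subject -> 'young'/'older'. Subjects missing a condition are
    dropped. Returns a dict with:

    * ``mode_diff`` [subject, f, t] (IP - AP) and ``labels``: between-group
      test of these = the interaction ([IP-AP]_young - [IP-AP]_older);
    * ``pooled`` [subject, f, t] (mean over modes): between-group test =
      group main effect (young - older);
    * ``mode_diff_all``: one-sample test = mode main effect (IP - AP).
    """
    diffs, pooled, labels, subjects = [], [], [], []
    for sub, conds in z_maps.items():
        if "into_IP" not in conds or "into_AP" not in conds:
            continue
        diffs.append(conds["into_IP"] - conds["into_AP"])
        pooled.append((conds["into_IP"] + conds["into_AP"]) / 2.0)
        labels.append(groups[sub])
        subjects.append(sub)
    return {
        "mode_diff": np.stack(diffs),
        "pooled": np.stack(pooled),
        "labels": np.array(labels),
        "subjects": subjects,
    }
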