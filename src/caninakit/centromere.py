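"""Functional centromere calling, composition, classification and metaplots.

Centromeres are annotated from CENH3 ChIP enrichment (log2[CENH3/H3])
as the span between the outermost enrichment peaks: windows exceeding
a chromosome-wise mean + k*sd threshold form peak runs, runs closer
than ``merge_gap`` are merged, and the merged cluster containing the
chromosome-wide enrichment maximum defines the centromere interval.
Repeat composition inside the interval (CANR4 satellite, ATHILA
retrotransposon, cenLTR tandem arrays, in bp) drives a bimodal
classification: large satellite-based centromeres versus smaller
retrotransposon-based ones, with LTR-derived tandem arrays as a third,
rarer type.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CaninakitError
from .genome_map import GenomeMap

REPEAT_FAMILY_GROUP = {
    "CANR4": "canr4",
    "ATHILA": "athila",
    "ATHILA_LTR": "athila",
    "cenLTR1": "cenltr",
    "cenLTR2": "cenltr",
    "cenLTR3": "cenltr",
    "cenLTR4": "cenltr",
}

# classification defaults (fractions of centromere length / absolute bp)
F_SAT_DEFAULT = 0.30       # CANR4 fraction for a satellite-based call
MIN_CENLTR_ARRAY = 50_000  # bp of cenLTR tandem array for a cenLTR-based call
F_TE_DEFAULT = 0.20        # ATHILA fraction for a retrotransposon-based call


@dataclass
class SignalTrack:
    """Tiled per-chromosome windowed signal (depth, log2 ratio, %, ...)."""

    df: pd.DataFrame  # columns: chrom, start0, end, value
    kind: str
    window_size: int

    def per_chrom(self):
        return self.df.groupby("chrom", sort=False)

    def chrom_values(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def to_bedgraph(self, path, header_comment=None):
        from .io import write_bedgraph

        write_bedgraph(self.df, path, header_comment=header_comment)

    @classmethod
    def from_bedgraph(cls, path, kind: str) -> "SignalTrack":
        from .io import read_bedgraph

        df = read_bedgraph(path)
        sizes = (df["end"] - df["start0"])
        window = int(sizes.mode().iloc[0]) if len(df) else 0
        return cls(df=df, kind=kind, window_size=window)


@dataclass
class CentromereInterval:
    chrom: str
    start0: int
    end: int
    cenh3_abundance: float
    max_position: int

    @property
    def length(self) -> int:
        return self.end - self.start0


@dataclass
class CentromereProfile:
    interval: CentromereInterval
    canr4_bp: int = 0
    athila_bp: int = 0
    cenltr_bp: int = 0
    other_bp: int = 0
    cls: Optional[str] = None

    def as_row(self) -> dict:
        iv = self.interval
        return {"chrom": iv.chrom, "start0": iv.start0, "end": iv.end,
                "length": iv.length, "canr4_bp": self.canr4_bp,
                "athila_bp": self.athila_bp, "cenltr_bp": self.cenltr_bp,
                "other_bp": self.other_bp, "cenh3_abundance": iv.cenh3_abundance,
                "class": self.cls}


@dataclass
class RegressionResult:
    slope: Optional[float]
    intercept: Optional[float]
    r_squared: Optional[float]
    spearman_rho: Optional[float]
    n: int
    diagnostic: Optional[str] = None


@dataclass
class MetaplotProfile:
    """Per-subgenome binned signal over scaled telomere->centromere coordinate."""

    coords: np.ndarray                       # bin centers in [0, 1]
    profiles: dict                           # (subgenome, kind) -> value array
    scaling: dict                            # kind -> (global_min, global_max)
    proximity_fraction: float = 0.10

    def proximity_view(self, subgenome: str, kind: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.coords >= 1.0 - self.proximity_fraction
        return self.coords[mask], self.profiles[(subgenome, kind)][mask]


# ------------------------------------------------------------------ tracks
def enrichment_track(cenh3: SignalTrack, h3: SignalTrack,
                     pseudocount: float = 0.01,
                     normalize: str = "none") -> SignalTrack:
    """log2((CENH3 + pc) / (H3 + pc)) over matching windows.

    ``normalize="none"`` assumes both tracks are already depth-normalized
    (the generator emits them that way, mirroring per-library read-count
    scaling); ``"mass"`` additionally rescales each track to equal total
    mass before the ratio.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    a, b = cenh3.df, h3.df
    if len(a) != len(b) or not (
            a[["chrom", "start0", "end"]].reset_index(drop=True)
            .equals(b[["chrom", "start0", "end"]].reset_index(drop=True))):
        raise CaninakitError("enrichment_track: window grids do not match")
    x = a["value"].to_numpy(dtype=float)
    y = b["value"].to_numpy(dtype=float)
    if normalize == "mass":
        tx, ty = x.sum(), y.sum()
        if tx <= 0 or ty <= 0:
            raise CaninakitError("enrichment_track: zero total mass")
        scale = (tx + ty) / 2
        x = x * (scale / tx)
        y = y * (scale / ty)
    elif normalize != "none":
        raise ValueError(f"unknown normalize mode {normalize!r}")
    out = a[["chrom", "start0", "end"]].copy()
    out["value"] = np.log2((x + pseudocount) / (y + pseudocount))
    return SignalTrack(df=out, kind="log2_ratio", window_size=cenh3.window_size)


# ------------------------------------------------------------------ calling
def call_centromere(track: SignalTrack, threshold_k: float = 2.0,
                    merge_gap: int = 100_000,
                    abundance: str = "positive") -> list[CentromereInterval]:
    """Call one centromere interval per chromosome from a log2-ratio track.

    Peaks are maximal runs of windows with value >= mean + k*sd
    (chromosome-wise); runs separated by less than ``merge_gap`` are
    merged, and the merged cluster containing the chromosome-wide
    maximum spans the centromere ("between the outermost peaks").
    Chromosomes with no window above threshold yield no interval
    (reported by omission, not fatally).

    ``abundance`` selects how CENH3 abundance is summed over the call:
    ``"positive"`` (default) sums positive log2 values only, ``"raw"``
    sums all values.
    """
    if abundance not in ("positive", "raw"):
        raise ValueError("abundance must be 'positive' or 'raw'")
    calls = []
    for chrom, sub in track.per_chrom():
        v = sub["value"].to_numpy(dtype=float)
        starts = sub["start0"].to_numpy()
        ends = sub["end"].to_numpy()
        if v.std() == 0:  # flat track: no peaks, no centromere
            continue
        thr = v.mean() + threshold_k * v.std()
        above = v >= thr
        if not above.any():
            continue
        # maximal runs of above-threshold windows
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_bounds = np.split(idx, breaks + 1)
        runs = [(int(r[0]), int(r[-1])) for r in run_bounds]
        # merge runs closer than merge_gap (genomic distance)
        merged = [list(runs[0])]
        for lo, hi in runs[1:]:
            gap = starts[lo] - ends[merged[-1][1]]
            if gap < merge_gap:
                merged[-1][1] = hi
            else:
                merged.append([lo, hi])
        argmax = int(np.argmax(v))
        cluster = next((m for m in merged if m[0] <= argmax <= m[1]), None)
        if cluster is None:  # argmax below threshold cannot happen, but be safe
            cluster = max(merged, key=lambda m: v[m[0]:m[1] + 1].max())
        lo, hi = cluster
        vv = v[lo:hi + 1]
        abund = float(np.clip(vv, 0, None).sum() if abundance == "positive" else vv.sum())
        calls.append(CentromereInterval(
            chrom=chrom, start0=int(starts[lo]), end=int(ends[hi]),
            cenh3_abundance=abund, max_position=int(starts[argmax])))
    return calls


# -------------------------------------------------------------- composition
def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent [start, end) rows (sorted by start)."""
    if len(iv) == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0])]
    out = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


def repeat_composition(interval: CentromereInterval,
                       annotation: pd.DataFrame) -> CentromereProfile:
    """Per-family bp of annotation within the interval.

    Same-group features (e.g. an ATHILA element and its nested LTR
    features) are merged before clipping, so the bp fields are
    invariant to feature splitting.
    """
    sub = annotation[(annotation["chrom"] == interval.chrom)
                     & (annotation["end"] > interval.start0)
                     & (annotation["start0"] < interval.end)]
    bp = {"canr4": 0, "athila": 0, "cenltr": 0, "other": 0}
    fams = sub["family"] if "family" in sub.columns else pd.Series([], dtype=str)
    groups = fams.map(lambda f: REPEAT_FAMILY_GROUP.get(f, "other"))
    for group in bp:
        rows = sub[groups == group]
        if not len(rows):
            continue
        merged = _merge_intervals(rows[["start0", "end"]].to_numpy(dtype=np.int64))
        clipped = np.clip(merged, interval.start0, interval.end)
        bp[group] = int((clipped[:, 1] - clipped[:, 0]).clip(min=0).sum())
    return CentromereProfile(interval=interval, canr4_bp=bp["canr4"],
                             athila_bp=bp["athila"], cenltr_bp=bp["cenltr"],
                             other_bp=bp["other"])


def classify_composition(canr4_bp: int, athila_bp: int, cenltr_bp: int,
                         length: int, f_sat: float = F_SAT_DEFAULT,
                         min_array: int = MIN_CENLTR_ARRAY,
                         f_te: float = F_TE_DEFAULT) -> str:
    """Bimodal(-plus) centromere class from repeat composition.

    Satellite-based if CANR4 covers >= ``f_sat`` of the interval; else
    cenLTR-based if the LTR-derived tandem array reaches ``min_array``
    bp; else ATHILA-based if ATHILA covers >= ``f_te``; else mixed.
    """
    if length <= 0:
        raise CaninakitError("classify_centromere: zero-length interval")
    if canr4_bp / length >= f_sat:
        return "CANR4-based"
    if cenltr_bp >= min_array:
        return "cenLTR-based"
    if athila_bp / length >= f_te:
        return "ATHILA-based"
    return "mixed"


def classify_centromere(profile: CentromereProfile, f_sat: float = F_SAT_DEFAULT,
                        min_array: int = MIN_CENLTR_ARRAY,
                        f_te: float = F_TE_DEFAULT) -> CentromereProfile:
    profile.cls = classify_composition(profile.canr4_bp, profile.athila_bp,
                                       profile.cenltr_bp, profile.interval.length,
                                       f_sat=f_sat, min_array=min_array, f_te=f_te)
    return profile


def profiles_frame(profiles: Sequence[CentromereProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.as_row() for p in profiles])


# ------------------------------------------------------------- regression
def canr4_cenh3_regression(profiles: Sequence[CentromereProfile] | pd.DataFrame
                           ) -> RegressionResult:
    """OLS of CENH3 abundance on CANR4 bp across centromeres, plus Spearman."""
    df = profiles if isinstance(profiles, pd.DataFrame) else profiles_frame(profiles)
    if len(df) < 3:
        raise CaninakitError("regression requires at least 3 centromeres")
    x = df["canr4_bp"].to_numpy(dtype=float)
    y = df["cenh3_abundance"].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        return RegressionResult(None, None, None, None, len(df),
                                diagnostic="constant predictor: r_squared undefined")
    fit = stats.linregress(x, y)
    rho = stats.spearmanr(x, y).statistic
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            spearman_rho=float(rho), n=len(df))


# --------------------------------------------------------------- metaplots
def metaplot(tracks: Mapping[str, SignalTrack],
             calls: Sequence[CentromereInterval],
             genome_map: GenomeMap,
             n_bins: int = 100,
             proximity_fraction: float = 0.10,
             smooth_bandwidth: int = 0,
             methylation_kinds: tuple = ("methylation_CpG", "methylation_CHG",
                                         "methylation_CHH")) -> MetaplotProfile:
    """Telomere-to-centromere scaled, arm-mirrored, subgenome-averaged profiles.

    Each arm is scaled so the telomere maps to 0 and the centromere
    (enrichment argmax) to 1; p- and q-arm bin vectors are averaged
    within a chromosome, then across the chromosomes of a subgenome.
    Signals are min-max scaled to [0, 1] using the global extremes of
    the binned values, except methylation which keeps raw percentages.
    Smoothing (a moving average over ``smooth_bandwidth`` bins) is
    cosmetic and applied last.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    cen_by_chrom = {c.chrom: c for c in calls}
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    raw: dict[tuple, list[np.ndarray]] = {}
    for kind, track in tracks.items():
        for chrom, sub in track.per_chrom():
            if chrom not in cen_by_chrom:
                warnings.warn(f"metaplot: no centromere call for {chrom}; skipped")
                continue
            rec = genome_map.chrom(chrom)
            cen = cen_by_chrom[chrom].max_position
            mids = (0.5 * (sub["start0"] + sub["end"])).to_numpy(dtype=float)
            vals = sub["value"].to_numpy(dtype=float)
            arm_profiles = []
            for arm_mask, scaled in (
                    (mids <= cen, 1.0 - (cen - mids[mids <= cen]) / max(cen, 1)),
                    (mids > cen, 1.0 - (mids[mids > cen] - cen)
                     / max(rec.length - cen, 1))):
                if not arm_mask.any():
                    continue
                av = vals[arm_mask]
                which = np.clip(np.digitize(scaled, edges) - 1, 0, n_bins - 1)
                sums = np.bincount(which, weights=av, minlength=n_bins)
                cnts = np.bincount(which, minlength=n_bins)
                with np.errstate(invalid="ignore"):
                    prof = sums / cnts
                # fill empty bins by interpolation over the arm
                if np.isnan(prof).any():
                    good = ~np.isnan(prof)
                    if good.sum() >= 2:
                        prof = np.interp(centers, centers[good], prof[good])
                    else:
                        continue
                arm_profiles.append(prof)
            if arm_profiles:
                chrom_profile = np.mean(arm_profiles, axis=0)
                raw.setdefault((rec.subgenome, kind), []).append(chrom_profile)

    profiles, scaling = {}, {}
    for kind in tracks:
        per_sub = {sub: np.mean(v, axis=0)
                   for (sub, k), v in raw.items() if k == kind}
        if not per_sub:
            continue
        allv = np.concatenate(list(per_sub.values()))
        gmin, gmax = float(allv.min()), float(allv.max())
        scaling[kind] = (gmin, gmax)
        for sub, prof in per_sub.items():
            if kind not in methylation_kinds:
                if gmax > gmin:
                    prof = (prof - gmin) / (gmax - gmin)
                elif gmax > 0:  # constant positive signal scales to 1
                    prof = prof / gmax
            if smooth_bandwidth > 1:
                kern = np.ones(smooth_bandwidth) / smooth_bandwidth
                prof = np.convolve(prof, kern, mode="same")
            profiles[(sub, kind)] = prof
    return MetaplotProfile(coords=centers, profiles=profiles, scaling=scaling,
                           proximity_fraction=proximity_fraction)


def metaplot_frame(mp: MetaplotProfile) -> pd.DataFrame:
    rows = []
    for (sub, kind), prof in mp.profiles.items():
        for c, v in zip(mp.coords, prof):
            rows.append((sub, kind, float(c), float(v)))
    return pd.DataFrame(rows, columns=["subgenome", "kind", "scaled_coord", "value"])


# -------------------------------------------------------------- methylation
def methylation_summary(calls: pd.DataFrame, window_size: int,
                        chrom_lengths: Mapping[str, int]) -> dict[str, SignalTrack]:
    """Window %-methylation per context from per-cytosine calls.

    ``calls`` columns: chrom, pos0, context (CpG/CHG/CHH), methylated,
    unmethylated (counts).  Windows with no cytosine calls get NaN,
    not zero.
    """
    contexts = sorted(calls["context"].unique())
    bad = set(contexts) - {"CpG", "CHG", "CHH"}
    if bad:
        raise CaninakitError(f"unknown methylation context(s): {sorted(bad)}")
    out = {}
    for ctx in contexts:
        sub = calls[calls["context"] == ctx]
        rows = []
        for chrom, length in chrom_lengths.items():
            n_win = int(np.ceil(length / window_size))
            meth = np.zeros(n_win)
            tot = np.zeros(n_win)
            cc = sub[sub["chrom"] == chrom]
            if len(cc):
                w = (cc["pos0"].to_numpy() // window_size).astype(int)
                np.add.at(meth, w, cc["methylated"].to_numpy(dtype=float))
                np.add.at(tot, w, (cc["methylated"] + cc["unmethylated"])
                          .to_numpy(dtype=float))
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = np.where(tot > 0, 100.0 * meth / tot, np.nan)
            starts = np.arange(n_win) * window_size
            ends = np.minimum(starts + window_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start0": starts,
                                      "end": ends, "value": pct}))
        out[f"methylation_{ctx}"] = SignalTrack(
            df=pd.concat(rows, ignore_index=True),
            kind=f"methylation_{ctx}", window_size=window_size)
    return out
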