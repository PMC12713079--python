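"""Spikelet-trajectory geometry: quartic profiles and I/N/D spike typing.

Wheat spikes carry a variable number of spikelets bottom-to-top, so raw
per-spikelet measurements (angle to the rachis in degrees, gap along the
rachis in mm) are not directly comparable across lines.  The pipeline
standardizes them:

1. map each line's ordered spikelets onto the common axis [0, 20]
   (0 = bottom, 20 = top);
2. fit a degree-4 polynomial trajectory by least squares;
3. evaluate it at the 21 integer nodes 0..20;
4. average the nodes over four fixed regions -- bottom (3 nodes),
   lower-middle (8), upper-middle (8), top (2);
5. compare each region mean against the population's region mean and code
   it I (increased), N (approximately unchanged) or D (decreased),
   yielding a 4-letter spike-type code from the 3^4 = 81-code space.

Profiles can also be clustered directly on their 21-node vectors (Ward
linkage on Euclidean distance).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

REGION_SIZES = (3, 8, 8, 2)
REGION_NAMES = ("bottom", "lower_middle", "upper_middle", "top")
CODE_LETTERS = ("I", "N", "D")
N_NODES = 21


@dataclass
class SpikeProfile:
    """One line's standardized trajectory for one trait."""

    line_id: str
    trait: str
    raw_values: np.ndarray
    positions: np.ndarray
    coefficients: np.ndarray  # ascending powers, length 5
    nodes: np.ndarray         # values at 0..20
    region_means: np.ndarray  # length 4, bottom -> top


def normalize_positions(n_spikelets: int) -> np.ndarray:
    """Map spikelet ranks 1..n onto [0, 20]: rank i -> 20*(i-1)/(n-1)."""
    if n_spikelets < 5:
        raise ValueError("need at least 5 spikelets for a quartic fit")
    return 20.0 * np.arange(n_spikelets) / (n_spikelets - 1)


def fit_quartic(positions: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Least-squares degree-4 polynomial; coefficients in ascending powers.

    Exact interpolation when exactly 5 distinct positions are given.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(np.unique(positions)) < 5:
        raise ValueError("need >= 5 distinct positions for a quartic fit")
    return np.polynomial.polynomial.polyfit(positions, values, deg=4)


def interpolate_nodes(coefficients: np.ndarray) -> np.ndarray:
    """Evaluate the quartic at the 21 integer nodes 0..20."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (5,):
        raise ValueError("expected 5 polynomial coefficients")
    return np.polynomial.polynomial.polyval(np.arange(N_NODES, dtype=float),
                                            coefficients)


def partition_regions(nodes: np.ndarray,
                      sizes: tuple[int, ...] = REGION_SIZES) -> np.ndarray:
    """Mean node value per region, bottom to top."""
    nodes = np.asarray(nodes, dtype=float)
    if len(nodes) != sum(sizes):
        raise ValueError(f"expected {sum(sizes)} node values, got {len(nodes)}")
    bounds = np.cumsum((0,) + tuple(sizes))
    return np.array([nodes[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])


def line_profile(line_id: str, values: np.ndarray, trait: str = "angle") -> SpikeProfile:
    """Full standardization pipeline for one line's ordered measurements."""
    values = np.asarray(values, dtype=float)
    positions = normalize_positions(len(values))
    coef = fit_quartic(positions, values)
    nodes = interpolate_nodes(coef)
    return SpikeProfile(
        line_id=line_id, trait=trait, raw_values=values, positions=positions,
        coefficients=coef, nodes=nodes, region_means=partition_regions(nodes),
    )


def profiles_from_table(table: pd.DataFrame, trait: str = "angle") -> pd.DataFrame:
    """21-node profile per line from a long-form spikelet table.

    ``table`` has columns (line_id, spikelet_index, <trait>); rows are
    ordered bottom-to-top by spikelet_index.  Lines with fewer than 5
    spikelets are excluded (logged).  Returns a lines x 21 DataFrame.
    """
    rows = {}
    excluded = []
    for line_id, grp in table.groupby("line_id", sort=True):
        vals = grp.sort_values("spikelet_index")[trait].to_numpy(dtype=float)
        if len(vals) < 5:
            excluded.append(line_id)
            continue
        rows[line_id] = line_profile(str(line_id), vals, trait).nodes
    if excluded:
        logger.info("profiles_from_table: %d lines with <5 spikelets excluded",
                    len(excluded))
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=[f"node_{i}" for i in range(N_NODES)])
    out.index.name = "line_id"
    return out


# ---------------------------------------------------------------------------
# I/N/D typing


def classify_ind(
    region_means: np.ndarray,
    population_means: np.ndarray,
    rel_tolerance: float = 0.025,
) -> str:
    """Code each region I/N/D against the population's region mean.

    I when the line mean exceeds the population mean by more than the
    relative tolerance band, D when it falls below it, N inside the band.
    A zero population mean makes the relative band degenerate; the band
    then falls back to ``rel_tolerance`` in absolute units (logged).
    """
    region_means = np.asarray(region_means, dtype=float)
    population_means = np.asarray(population_means, dtype=float)
    if region_means.shape != population_means.shape or len(region_means) != 4:
        raise ValueError("expected 4 region means for line and population")
    letters = []
    for m, pop in zip(region_means, population_means):
        if pop == 0:
            logger.info("classify_ind: zero population mean; absolute tolerance used")
            hi, lo = rel_tolerance, -rel_tolerance
        else:
            hi = abs(pop) * rel_tolerance
            lo = -hi
        diff = m - pop
        if diff > hi:
            letters.append("I")
        elif diff < lo:
            letters.append("D")
        else:
            letters.append("N")
    return "".join(letters)


def enumerate_code_space() -> list[str]:
    """All 3^4 = 81 possible spike-type codes, lexicographic order."""
    return ["".join(c) for c in itertools.product(sorted(CODE_LETTERS), repeat=4)]


def type_frequencies(codes: list[str] | pd.Series) -> pd.DataFrame:
    """Counts and proportions per observed spike-type code."""
    valid = set(enumerate_code_space())
    codes = list(codes)
    for c in codes:
        if c not in valid:
            raise ValueError(f"invalid spike-type code {c!r}")
    counts = pd.Series(codes).value_counts().sort_index()
    out = pd.DataFrame({"count": counts, "proportion": counts / counts.sum()})
    out.index.name = "code"
    return out


def classify_population(profiles: pd.DataFrame,
                        rel_tolerance: float = 0.025,
                        population_means: np.ndarray | None = None) -> pd.Series:
    """Spike-type code per line against the population's region means.

    ``population_means`` defaults to the per-region mean over all lines'
    region means (the per-region population average).
    """
    region = np.stack([partition_regions(row.to_numpy())
                       for _, row in profiles.iterrows()])
    if population_means is None:
        population_means = region.mean(axis=0)
    codes = [classify_ind(r, population_means, rel_tolerance) for r in region]
    return pd.Series(codes, index=profiles.index, name="spike_type")


# ---------------------------------------------------------------------------
# Clustering


def cluster_profiles(profiles: pd.DataFrame | np.ndarray, k: int | None = None,
                     cut_height: float | None = None) -> np.ndarray:
    """Ward-linkage hierarchical clustering of 21-node profiles.

    Cut either at ``k`` clusters or at ``cut_height`` on the Euclidean
    Ward dendrogram; deterministic.
    """
    X = profiles.to_numpy() if isinstance(profiles, pd.DataFrame) else np.asarray(profiles)
    if len(X) < 2:
        raise ValueError("need at least 2 lines to cluster")
    if k is not None and k > len(X):
        raise ValueError("more clusters requested than lines available")
    Z = linkage(X, method="ward", metric="euclidean")
    if k is not None:
        return fcluster(Z, t=k, criterion="maxclust")
    if cut_height is not None:
        return fcluster(Z, t=cut_height, criterion="distance")
    raise ValueError("specify k or cut_height")
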