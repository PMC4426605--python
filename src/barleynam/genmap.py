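"""Genetic map container used throughout the package.

A genetic map is a table of markers with a chromosome label and a genetic
position in centimorgan (cM). Positions within a chromosome are kept sorted;
recombination probabilities between adjacent markers follow the Haldane map
function (no crossover interference).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "haldane_r", "default_map"]


def haldane_r(d_cm):
    """Recombination fraction for a map distance in cM under Haldane's map
    function, r = (1 - exp(-2d/100)) / 2. Vectorised; bounded by 0.5."""
    d = np.asarray(d_cm, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


class GeneticMap:
    """Ordered marker map.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``marker``, ``chromosome``, ``position_cm``. Marker ids must
        be unique, positions non-negative. The table is sorted by chromosome
        (order of first appearance) and position.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"marker", "chromosome", "position_cm"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        tab = table.copy()
        if tab["marker"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        if (tab["position_cm"] < 0).any():
            raise ValueError("negative map positions")
        chrom_order = {c: i for i, c in enumerate(pd.unique(tab["chromosome"]))}
        tab["_corder"] = tab["chromosome"].map(chrom_order)
        tab = tab.sort_values(["_corder", "position_cm"], kind="mergesort")
        tab = tab.drop(columns="_corder").reset_index(drop=True)
        self.table = tab
        self.markers = tab["marker"].to_numpy()
        self.chromosome = tab["chromosome"].to_numpy()
        self.position = tab["position_cm"].to_numpy(dtype=float)
        self._index = pd.Series(np.arange(len(tab)), index=tab["marker"])

    def __len__(self):
        return len(self.table)

    def index_of(self, marker) -> int:
        return int(self._index[marker])

    @property
    def chromosomes(self):
        return list(pd.unique(self.chromosome))

    def chrom_slices(self):
        """List of (chromosome, slice) pairs covering the sorted marker order."""
        out = []
        start = 0
        for c in self.chromosomes:
            n = int((self.chromosome == c).sum())
            out.append((c, slice(start, start + n)))
            start += n
        return out

    def recomb_fractions(self):
        """Per-marker recombination fraction with the *previous* marker.

        The first marker of each chromosome gets r = 0.5 so that chromosomes
        assort independently when a gamete is built by a cumulative-crossover
        walk along this vector.
        """
        r = np.empty(len(self), dtype=float)
        for _, sl in self.chrom_slices():
            pos = self.position[sl]
            r_chr = haldane_r(np.diff(pos))
            r[sl] = np.concatenate([[0.5], r_chr])
        return r

    def nearest_marker(self, chromosome, position_cm) -> str:
        """Marker id closest to a chromosome/position anchor."""
        mask = self.chromosome == chromosome
        if not mask.any():
            raise KeyError(f"chromosome {chromosome!r} not in map")
        idx = np.flatnonzero(mask)
        best = idx[np.argmin(np.abs(self.position[idx] - position_cm))]
        return self.markers[best]

    def distance(self, marker_a, marker_b):
        """Genetic distance in cM, or ``inf`` for inter-chromosomal pairs."""
        ia, ib = self.index_of(marker_a), self.index_of(marker_b)
        if self.chromosome[ia] != self.chromosome[ib]:
            return np.inf
        return abs(self.position[ia] - self.position[ib])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def default_map(n_markers: int = 2000, n_chromosomes: int = 7,
                length_cm: float = 150.0) -> GeneticMap:
    """Uniformly spaced stand-in genome: 7 barley-like chromosomes (1H..7H)
    of 150 cM, markers evenly spread. Marker counts per chromosome differ by
    at most one so any total can be requested (up to chip scale)."""
    base, rem = divmod(n_markers, n_chromosomes)
    rows = []
    for ci in range(n_chromosomes):
        n = base + (1 if ci < rem else 0)
        chrom = f"{ci + 1}H"
        pos = np.linspace(0.0, length_cm, n)
        for j, p in enumerate(pos):
            rows.append((f"M_{chrom}_{j:04d}", chrom, round(float(p), 4)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"]))
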