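"""Post-analysis: aggregate snippet pileups, one-to-one jet-set matching
(Venn counts via maximum-weight matching of IoU edges), and stratified random
regions."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import MultiPoint
from skimage.transform import resize

SNIPPET_SIZE = 100


def snippet_resolution(start_bp: int, end_bp: int, available_resolutions) -> int:
    """Coarsest available resolution giving at least SNIPPET_SIZE bins over
    the span; falls back to the finest available when none does."""
    if end_bp <= start_bp:
        raise ValueError("end must exceed start")
    res = sorted(int(r) for r in available_resolutions)
    if not res:
        raise ValueError("no resolutions available")
    span = end_bp - start_bp
    fitting = [r for r in res if span / r >= SNIPPET_SIZE]
    return max(fitting) if fitting else min(res)


def aggregate_snippets(spans: Sequence[tuple], matrices: dict) -> np.ndarray:
    """Element-wise mean of per-jet square snippets resized to 100 x 100.

    ``spans`` are (start_bp, end_bp) pairs; ``matrices`` maps resolution (bp)
    to a :class:`~chromjet.contact_image.ContactMatrix` (or dense array) for
    the chromosome.  Each jet uses the coarsest resolution giving >= 100 bins
    (bilinear resize); spans outside the matrix are skipped with a warning.
    """
    import warnings

    if len(spans) == 0:
        raise ValueError("need at least one jet span")
    acc = np.zeros((SNIPPET_SIZE, SNIPPET_SIZE))
    count = 0
    for (start, end) in spans:
        r = snippet_resolution(start, end, matrices.keys())
        M = matrices[r]
        A = M.values if hasattr(M, "values") else np.asarray(M, dtype=float)
        lo, hi = int(start // r), int(np.ceil(end / r))
        if lo < 0 or hi > A.shape[0] or hi - lo < 2:
            warnings.warn(f"span ({start}, {end}) outside matrix; skipped")
            continue
        snip = A[lo:hi, lo:hi]
        acc += resize(snip, (SNIPPET_SIZE, SNIPPET_SIZE), order=1,
                      mode="edge", anti_aliasing=False)
        count += 1
    if count == 0:
        raise ValueError("all spans fell outside the matrix")
    return acc / count


@dataclass
class JetMatch:
    """One-to-one matches between two jet sets with their IoU weights."""

    pairs: list = field(default_factory=list)   # (index_a, index_b, iou)
    unmatched_a: list = field(default_factory=list)
    unmatched_b: list = field(default_factory=list)

    @property
    def venn(self) -> tuple:
        """(common, A-only, B-only)."""
        return len(self.pairs), len(self.unmatched_a), len(self.unmatched_b)


def jet_polygon(points_bp: np.ndarray, buffer_bp: float):
    """Buffered footprint of a jet in genomic (bp x bp) space: the ridge's
    (anchor1, anchor2) point set dilated by its mean width."""
    return MultiPoint([tuple(p) for p in np.atleast_2d(points_bp)]).buffer(buffer_bp)


def polygons_from_summary(summary, resolution: int):
    """Jet footprints from a summary table (as written by the output module).

    Each jet's 2D extent is the segment from its diagonal origin
    (origin_bin, origin_bin) to its tip contact (origin_bin, tip_bin) in bp
    space, buffered by the jet's mean width.  Returns (polygons, chromosomes)
    for :func:`match_jet_sets`.
    """
    polys, chroms = [], []
    for _, row in summary.iterrows():
        o = float(row["origin_bin"]) * resolution
        t = float(row["tip_bin"]) * resolution
        n_pts = 16
        xs = np.linspace(o, (o + t) / 2.0, n_pts)
        ys = np.linspace(o, t, n_pts)
        buffer_bp = max(float(row.get("width_mean", 1.0)), 1.0) * resolution
        polys.append(jet_polygon(np.column_stack([xs, ys]), buffer_bp))
        chroms.append(row["chromosome"])
    return polys, chroms


def match_jet_sets(polys_a: Sequence, polys_b: Sequence,
                   chroms_a: Optional[Sequence] = None,
                   chroms_b: Optional[Sequence] = None) -> JetMatch:
    """Optimal one-to-one pairing of two jet sets by IoU maximum-weight
    matching, stratified by chromosome when chromosome labels are given.

    ``polys_*`` are shapely geometries (see :func:`jet_polygon`).
    """
    na, nb = len(polys_a), len(polys_b)
    chroms_a = list(chroms_a) if chroms_a is not None else ["*"] * na
    chroms_b = list(chroms_b) if chroms_b is not None else ["*"] * nb
    G = nx.Graph()
    G.add_nodes_from(("a", i) for i in range(na))
    G.add_nodes_from(("b", j) for j in range(nb))
    for i in range(na):
        for j in range(nb):
            if chroms_a[i] != chroms_b[j]:
                continue
            inter = polys_a[i].intersection(polys_b[j]).area
            if inter <= 0:
                continue
            union = polys_a[i].union(polys_b[j]).area
            G.add_edge(("a", i), ("b", j), weight=inter / union)
    matching = nx.max_weight_matching(G)
    pairs = []
    for (u, v) in matching:
        if u[0] == "b":
            u, v = v, u
        pairs.append((u[1], v[1], G[u][v]["weight"]))
    pairs.sort()
    matched_a = {i for i, _, _ in pairs}
    matched_b = {j for _, j, _ in pairs}
    return JetMatch(pairs=pairs,
                    unmatched_a=[i for i in range(na) if i not in matched_a],
                    unmatched_b=[j for j in range(nb) if j not in matched_b])


def random_regions(jet_table, chrom_sizes: dict, seed: int = 0) -> list:
    """Per chromosome, draw as many uniformly placed intervals as there are
    jets, each with the median jet length; seed-deterministic.

    ``jet_table`` needs ``chromosome``, ``start_bp``, ``end_bp`` columns (a
    DataFrame or equivalent list of dicts).  Returns (chrom, start, end)
    tuples.
    """
    import pandas as pd

    df = pd.DataFrame(jet_table)
    if len(df) == 0:
        return []
    rng = np.random.default_rng(seed)
    length = int(np.median(df["end_bp"] - df["start_bp"]))
    out = []
    for chrom, grp in df.groupby("chromosome", sort=True):
        size = int(chrom_sizes[chrom])
        hi = max(size - length, 1)
        starts = rng.integers(0, hi, size=len(grp))
        out.extend((chrom, int(s), int(s) + length) for s in starts)
    return out
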