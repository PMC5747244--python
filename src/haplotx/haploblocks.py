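"""Delineation of LD blocks (haploblocks) around index GWAS SNPs.

A haploblock is the co-inherited region tagged by an index GWAS SNP.  Its
boundaries are located from a table of proxy SNPs (variants with known r²
to the index SNP) and a list of recombination hotspots, under one of two
rule sets:

* ``main`` — two-step: (1) extend from the index SNP to the most distant
  proxy with r² above the extension threshold on each side, clipped to a
  per-side cap (500 kb); (2) a side is *insufficient* when no proxy on that
  side shows r² below the sufficiency threshold (LD never decays, so the
  boundary cannot be located) — such a side is pushed out to the nearest
  recombination hotspot beyond the current boundary.
* ``pilot`` — extend to the most distant proxy above the threshold, then
  always extend both sides to the nearest hotspots, then clip the total
  block length to a 1-Mb cap.

Block coordinates are half-open; the end coordinate is the outermost
retained SNP position + 1, so the boundary SNP base is included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval, IntervalSet

SNP_CLASSES = ("index", "proxy", "gwas", "common")


@dataclass(frozen=True)
class SnpRecord:
    """A SNP with optional linkage (r²) to an index SNP."""

    snp_id: str
    chrom: str
    pos: int
    r2: float | None = None
    snp_class: str = "proxy"

    def __post_init__(self) -> None:
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")
        if self.snp_class not in SNP_CLASSES:
            raise ValueError(f"unknown SNP class {self.snp_class!r}")


@dataclass(frozen=True)
class Hotspot:
    """A recombination hotspot, reduced to a point position."""

    chrom: str
    pos: int


@dataclass(frozen=True)
class BlockRules:
    """Thresholds and caps governing block construction.

    hotspot_extension is "insufficient" (main design: extend only sides
    whose LD never decays) or "always" (pilot design).
    """

    r2_extend: float = 0.5
    r2_sufficient: float = 0.6
    side_cap_bp: int = 500_000
    total_cap_bp: int = 1_000_000
    hotspot_extension: str = "insufficient"

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_extend <= self.r2_sufficient <= 1.0):
            raise ValueError("require 0 < r2_extend <= r2_sufficient <= 1")
        if self.side_cap_bp <= 0 or self.total_cap_bp <= 0:
            raise ValueError("caps must be positive")
        if self.hotspot_extension not in ("insufficient", "always"):
            raise ValueError("hotspot_extension must be 'insufficient' or 'always'")


MAIN_RULES = BlockRules(hotspot_extension="insufficient")
PILOT_RULES = BlockRules(hotspot_extension="always")

BOUNDARY_RULES = ("proxy_extent", "hotspot", "cap")


@dataclass
class Haploblock:
    """An LD block with provenance of how each boundary was set."""

    region: GenomicInterval
    index_snp: SnpRecord
    left_rule: str
    right_rule: str
    params_used: str  # "pilot" or "main"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.region.start <= self.index_snp.pos < self.region.end):
            raise ValueError(
                f"block {self.region} does not contain its index SNP at {self.index_snp.pos}"
            )
        for rule in (self.left_rule, self.right_rule):
            if rule not in BOUNDARY_RULES:
                raise ValueError(f"unknown boundary rule {rule!r}")


def _nearest_hotspot_beyond(
    hotspots: Sequence[Hotspot], chrom: str, boundary: int, direction: int
) -> int | None:
    """Position of the hotspot nearest to `boundary` strictly beyond it.

    direction -1 = leftward (away from the index on the 5' side),
    +1 = rightward.  Hotspots inside the current block are ignored; ties in
    distance are impossible for distinct positions, and scanning keeps the
    smallest extension.
    """
    candidates = [
        h.pos
        for h in hotspots
        if h.chrom == chrom and (h.pos < boundary if direction < 0 else h.pos > boundary)
    ]
    if not candidates:
        return None
    return max(candidates) if direction < 0 else min(candidates)


def _side_proxies(index: SnpRecord, proxies: Iterable[SnpRecord], direction: int):
    if direction < 0:
        return [p for p in proxies if p.chrom == index.chrom and p.pos < index.pos]
    return [p for p in proxies if p.chrom == index.chrom and p.pos > index.pos]


def build_block_main(
    index: SnpRecord,
    proxies: Sequence[SnpRecord],
    hotspots: Sequence[Hotspot],
    rules: BlockRules = MAIN_RULES,
) -> Haploblock:
    """Two-step block construction with per-side cap and conditional hotspot extension.

    Only proxies within the per-side cap participate in the sufficiency
    test; the proxy extent itself is clipped to the cap.
    """
    warnings: list[str] = []
    bounds = {}
    rules_used = {}
    for direction, label in ((-1, "left"), (1, "right")):
        side = _side_proxies(index, proxies, direction)
        above = [p for p in side if p.r2 is not None and p.r2 > rules.r2_extend]
        if above:
            extreme = min(p.pos for p in above) if direction < 0 else max(p.pos for p in above)
        else:
            extreme = index.pos
        cap_pos = index.pos - rules.side_cap_bp if direction < 0 else index.pos + rules.side_cap_bp
        if direction < 0:
            boundary = max(extreme, cap_pos, 0)
            clipped = extreme < cap_pos
        else:
            boundary = min(extreme, cap_pos)
            clipped = extreme > cap_pos
        rule = "cap" if clipped else "proxy_extent"
        # Sufficiency: among within-cap proxies on this side, at least one
        # must have decayed below r2_sufficient; an empty side counts as
        # insufficient.
        in_cap = [
            p
            for p in side
            if (abs(p.pos - index.pos) <= rules.side_cap_bp) and p.r2 is not None
        ]
        sufficient = any(p.r2 < rules.r2_sufficient for p in in_cap)
        if rules.hotspot_extension == "insufficient" and not sufficient:
            hs = _nearest_hotspot_beyond(hotspots, index.chrom, boundary, direction)
            if hs is None:
                warnings.append(
                    f"{label} side insufficient but no hotspot beyond {boundary} on {index.chrom}"
                )
            else:
                boundary = hs
                rule = "hotspot"
        bounds[label] = boundary
        rules_used[label] = rule
    left, right = bounds["left"], bounds["right"]
    region = GenomicInterval(index.chrom, max(left, 0), right + 1)
    return Haploblock(region, index, rules_used["left"], rules_used["right"], "main", warnings)


def build_block_pilot(
    index: SnpRecord,
    proxies: Sequence[SnpRecord],
    hotspots: Sequence[Hotspot],
    rules: BlockRules = PILOT_RULES,
) -> Haploblock:
    """Proxy extent, unconditional hotspot extension, then total-length cap.

    The total cap is applied after hotspot extension by trimming each side
    proportionally to its overhang beyond half the cap from the index SNP.
    """
    warnings: list[str] = []
    bounds = {}
    rules_used = {}
    for direction, label in ((-1, "left"), (1, "right")):
        side = _side_proxies(index, proxies, direction)
        above = [p for p in side if p.r2 is not None and p.r2 > rules.r2_extend]
        if above:
            boundary = min(p.pos for p in above) if direction < 0 else max(p.pos for p in above)
        else:
            boundary = index.pos
        rule = "proxy_extent"
        hs = _nearest_hotspot_beyond(hotspots, index.chrom, boundary, direction)
        if hs is None:
            warnings.append(
                f"{label} side: no hotspot beyond {boundary} on {index.chrom}"
            )
        else:
            boundary = hs
            rule = "hotspot"
        bounds[label] = boundary
        rules_used[label] = rule
    left, right = bounds["left"], bounds["right"]
    length = right - left + 1
    if length > rules.total_cap_bp:
        half = rules.total_cap_bp // 2
        over_l = max(0, (index.pos - left) - half)
        over_r = max(0, (right - index.pos) - half)
        excess = length - rules.total_cap_bp
        if over_l + over_r > 0:
            trim_l = min(over_l, round(excess * over_l / (over_l + over_r)))
        else:  # degenerate: cap smaller than both half-sides combined
            trim_l = excess // 2
        trim_r = excess - trim_l
        if trim_r > over_r:  # push remainder back to the other side
            trim_l += trim_r - over_r
            trim_r = over_r
        left += trim_l
        right -= trim_r
        left = min(left, index.pos)
        right = max(right, index.pos)
        if trim_l > 0:
            rules_used["left"] = "cap"
        if trim_r > 0:
            rules_used["right"] = "cap"
    region = GenomicInterval(index.chrom, max(left, 0), right + 1)
    return Haploblock(region, index, rules_used["left"], rules_used["right"], "pilot", warnings)


@dataclass
class CollapsedRegions:
    """Non-redundant merged regions plus the index SNPs backing each region."""

    regions: IntervalSet
    contributors: list[list[str]]  # parallel to regions.intervals


def collapse_blocks(blocks: Sequence[Haploblock]) -> CollapsedRegions:
    """Merge possibly-overlapping blocks into a non-redundant region set."""
    merged = IntervalSet(b.region for b in blocks).merge()
    contributors: list[list[str]] = []
    for region in merged:
        ids = [
            b.index_snp.snp_id
            for b in blocks
            if b.region.overlaps(region)
        ]
        contributors.append(sorted(set(ids)))
    return CollapsedRegions(merged, contributors)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

PROXY_COLUMNS = ["index_snp_id", "proxy_snp_id", "chrom", "pos", "r2"]


def read_proxy_table(path: str | Path) -> pd.DataFrame:
    """Proxy-SNP TSV: index_snp_id, proxy_snp_id, chrom, pos, r2.

    The index SNP appears as its own proxy (r2 = 1) or is inferred as the
    row whose proxy_snp_id equals index_snp_id.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(PROXY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"proxy table missing columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_hotspots(path: str | Path) -> list[Hotspot]:
    """Hotspots from BED (point = interval start, i.e. the proximal edge is
    resolved during extension) or a two-column chrom/pos TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 3:
        # BED interval: reduce to midpoint-agnostic representative edges —
        # both edges are offered so extension can stop at the proximal one.
        out = []
        for _, row in df.iterrows():
            out.append(Hotspot(str(row[0]), int(row[1])))
            out.append(Hotspot(str(row[0]), int(row[2]) - 1))
        return out
    return [Hotspot(str(c), int(p)) for c, p in zip(df[0], df[1])]


def blocks_from_proxy_table(
    proxies: pd.DataFrame,
    hotspots: Sequence[Hotspot],
    rules: BlockRules,
    rule_set: str = "main",
) -> list[Haploblock]:
    """Build one block per index SNP in a long-format proxy table."""
    build = build_block_main if rule_set == "main" else build_block_pilot
    blocks = []
    for index_id, grp in proxies.groupby("index_snp_id", sort=True):
        self_rows = grp[grp["proxy_snp_id"] == index_id]
        if len(self_rows):
            row = self_rows.iloc[0]
            index = SnpRecord(str(index_id), str(row["chrom"]), int(row["pos"]), None, "index")
        else:
            raise ValueError(f"index SNP {index_id!r} has no self row in the proxy table")
        recs = [
            SnpRecord(str(r.proxy_snp_id), str(r.chrom), int(r.pos), float(r.r2), "proxy")
            for r in grp.itertuples()
            if r.proxy_snp_id != index_id
        ]
        blocks.append(build(index, recs, hotspots, rules))
    return blocks


def write_blocks_bed(blocks: Sequence[Haploblock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"{b.region.chrom}\t{b.region.start}\t{b.region.end}\t"
                f"{b.index_snp.snp_id}\t0\t.\n"
            )


def write_blocks_provenance(blocks: Sequence[Haploblock], path: str | Path) -> None:
    rows = [
        {
            "block_id": b.index_snp.snp_id,
            "chrom": b.region.chrom,
            "start": b.region.start,
            "end": b.region.end,
            "left_rule": b.left_rule,
            "right_rule": b.right_rule,
            "rule_set": b.params_used,
            "warnings": ";".join(b.warnings),
        }
        for b in blocks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
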