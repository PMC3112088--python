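"""Encoding FISH karyotype observations into the 30-segment character matrix.

Species-level observations (which chromosome pairs carry an rDNA cluster,
and where on the chromosome) are translated, through a homology map onto
the 30 ancestral orthologous segments, into a taxa x segments matrix with
states 0 (no cluster), 1 (pericentromeric cluster on the proximal region
of the segment), 2 (distal/subtelomeric cluster) and ? (missing data).

Chromosome tokens follow the karyotype-table notation: a bare label is a
pericentromeric cluster, a trailing ``*`` marks a subtelomeric one, ``~``
a cluster lying between centromere and telomere, and ``a.b`` a
Robertsonian metacentric whose both arms are scored as cluster-bearing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SEGMENTS",
    "ClusterSite",
    "SpeciesKaryotype",
    "HomologyMap",
    "ClusterSummary",
    "parse_chromosome_token",
    "expand_metacentric",
    "encode_matrix",
    "decode_matrix",
    "cluster_summary",
    "load_karyotypes",
    "load_homology_map",
]

#: canonical order of the 30 orthologous segments of the ancestral karyotype
SEGMENTS = (
    "1p", "1d", "2p", "2d", "3", "4", "5p", "5m", "5d", "6", "7",
    "8p", "8d", "9", "10p", "10d", "11p", "11d", "12", "12d",
    "13p", "13d", "14", "15p", "15d", "16", "17p", "17d", "18", "19",
)

POSITIONS = ("pericentromeric", "subtelomeric", "between")

_META_RE = re.compile(r"^([0-9A-Za-z]+)\.([0-9A-Za-z]+)$")


@dataclass(frozen=True)
class ClusterSite:
    chromosome: str
    position: str  # one of POSITIONS
    metacentric: bool = False

    def __post_init__(self):
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position class: {self.position}")


@dataclass
class SpeciesKaryotype:
    taxon: str
    subgenus: str
    diploid_2n: int
    sites: list[ClusterSite] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.sites)

    @property
    def n_sites(self) -> int:
        # a cluster pair contributes one site per homolog
        return 2 * len(self.sites)


def expand_metacentric(label: str) -> list[str]:
    """Arms of a Robertsonian metacentric noted ``a.b``; both carry the cluster."""
    m = _META_RE.match(label)
    if not m:
        raise ValueError(f"not metacentric notation (expected 'a.b'): {label!r}")
    return [m.group(1), m.group(2)]


def parse_chromosome_token(token: str) -> ClusterSite:
    token = token.strip()
    if not token:
        raise ValueError("empty chromosome token")
    if _META_RE.match(token):
        return ClusterSite(token, "pericentromeric", metacentric=True)
    if token.endswith("*"):
        return ClusterSite(token[:-1], "subtelomeric")
    if token.endswith("~"):
        return ClusterSite(token[:-1], "between")
    return ClusterSite(token, "pericentromeric")


@dataclass
class HomologyMap:
    """Chromosome -> orthologous-segment map, per taxon or taxon group.

    ``mapping`` is keyed by scope ("taxon:<name>" or "subgenus:<name>")
    then chromosome label, giving (proximal_segment, distal_segment);
    the sentinel segment "." marks a chromosome excluded from the matrix
    (e.g. the X, which is not one of the 30 autosomal segments).
    ``missing`` lists segments coded '?' for a taxon scope.
    """

    mapping: dict[str, dict[str, tuple[str, str]]]
    missing: dict[str, list[str]] = field(default_factory=dict)

    def lookup(self, kary: SpeciesKaryotype, chromosome: str) -> tuple[str, str]:
        for scope in (f"taxon:{kary.taxon}", f"subgenus:{kary.subgenus}"):
            entry = self.mapping.get(scope, {}).get(chromosome)
            if entry is not None:
                return entry
        raise KeyError(f"unmappable chromosome {chromosome!r} for taxon {kary.taxon!r}")

    def missing_segments(self, taxon: str) -> list[str]:
        return self.missing.get(f"taxon:{taxon}", [])


def _site_cells(kary, site, hmap, between_as_distal):
    """(segment, state) cells contributed by one cluster-bearing chromosome."""
    chroms = expand_metacentric(site.chromosome) if site.metacentric else [site.chromosome]
    cells = []
    for chrom in chroms:
        prox, dist = hmap.lookup(kary, chrom)
        if site.position == "subtelomeric" or (site.position == "between" and between_as_distal):
            seg, state = dist, "2"
        else:
            seg, state = prox, "1"
        if seg == ".":
            continue  # chromosome outside the 30-segment complement
        if seg not in SEGMENTS:
            raise KeyError(f"unknown segment {seg!r} (taxon {kary.taxon}, chromosome {chrom})")
        cells.append((seg, state))
    return cells


def encode_matrix(
    karyotypes: list[SpeciesKaryotype],
    hmap: HomologyMap,
    *,
    between_as_distal: bool = False,
) -> pd.DataFrame:
    """Build the taxa x 30-segment character matrix.

    Clusters lying between centromere and telomere are coded proximal
    (state 1) by default; ``between_as_distal`` switches them to state 2.
    Conflicting states for one (taxon, segment) cell raise.
    """
    rows = {}
    for kary in karyotypes:
        row = {seg: "0" for seg in SEGMENTS}
        for seg in hmap.missing_segments(kary.taxon):
            row[seg] = "?"
        for site in kary.sites:
            for seg, state in _site_cells(kary, site, hmap, between_as_distal):
                if row[seg] == "?":
                    raise ValueError(
                        f"cluster mapped to segment {seg} flagged missing for {kary.taxon}"
                    )
                if row[seg] not in ("0", state):
                    raise ValueError(
                        f"conflicting states for ({kary.taxon}, {seg}): "
                        f"{row[seg]} vs {state}"
                    )
                row[seg] = state
        if kary.taxon in rows:
            raise ValueError(f"duplicate taxon {kary.taxon}")
        rows[kary.taxon] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(SEGMENTS), dtype=object).fillna("0")


def decode_matrix(matrix: pd.DataFrame, hmap: HomologyMap, subgenus_of: dict[str, str]) -> list[SpeciesKaryotype]:
    """Inverse of :func:`encode_matrix` up to metacentric notation.

    Robertsonian arms come back as separate acrocentric entries, so
    decode(encode(k)) need not equal k, but re-encoding the decoded
    karyotypes reproduces the matrix exactly.
    """
    out = []
    for taxon in matrix.index:
        sub = subgenus_of[taxon]
        scope_maps = {}
        for scope in (f"taxon:{taxon}", f"subgenus:{sub}"):
            for chrom, (prox, dist) in hmap.mapping.get(scope, {}).items():
                scope_maps.setdefault(("1", prox), chrom)
                scope_maps.setdefault(("2", dist), chrom)
        sites = []
        for seg in matrix.columns:
            state = str(matrix.loc[taxon, seg])
            if state in ("0", "?"):
                continue
            key = (state, seg)
            if key not in scope_maps:
                raise KeyError(f"no chromosome maps to segment {seg} state {state} for {taxon}")
            chrom = scope_maps[key]
            pos = "pericentromeric" if state == "1" else "subtelomeric"
            sites.append(ClusterSite(chrom, pos))
        out.append(SpeciesKaryotype(taxon, sub, 0, sites))
    return out


@dataclass
class ClusterSummary:
    per_taxon: pd.DataFrame
    mean_pairs: float
    min_pairs: int
    max_pairs: int


def cluster_summary(karyotypes: list[SpeciesKaryotype]) -> ClusterSummary:
    """Per-taxon cluster-pair/site counts and their range and mean.

    Sites = 2 x pairs throughout (one site per homolog of each
    cluster-bearing pair).
    """
    rows = []
    for k in karyotypes:
        by_pos = {p: 0 for p in POSITIONS}
        for s in k.sites:
            by_pos[s.position] += 1
        rows.append(
            {
                "taxon": k.taxon,
                "subgenus": k.subgenus,
                "pairs": k.n_pairs,
                "sites": k.n_sites,
                "pericentromeric": by_pos["pericentromeric"],
                "subtelomeric": by_pos["subtelomeric"],
                "between": by_pos["between"],
            }
        )
    df = pd.DataFrame(rows).set_index("taxon")
    if len(df):
        return ClusterSummary(df, float(df["pairs"].mean()), int(df["pairs"].min()), int(df["pairs"].max()))
    return ClusterSummary(df, float("nan"), 0, 0)


def load_karyotypes(path: str | Path) -> list[SpeciesKaryotype]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    out = []
    for _, r in df.iterrows():
        tokens = [t for t in r["chromosomes"].split(",") if t.strip()]
        sites = [parse_chromosome_token(t) for t in tokens]
        out.append(SpeciesKaryotype(r["taxon"], r["subgenus"], int(r["diploid_2n"]), sites))
    return out


def load_homology_map(path: str | Path) -> HomologyMap:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    mapping: dict[str, dict[str, tuple[str, str]]] = {}
    missing: dict[str, list[str]] = {}
    for _, r in df.iterrows():
        scope = r["scope"]
        if r["kind"] == "missing":
            missing.setdefault(scope, []).extend(
                s for s in r["proximal_segment"].split(",") if s
            )
        else:
            mapping.setdefault(scope, {})[r["chromosome"]] = (
                r["proximal_segment"],
                r["distal_segment"] or r["proximal_segment"],
            )
    return HomologyMap(mapping=mapping, missing=missing)
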