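"""CAZyme family counting and polymer-degradation capability profiles.

dbCAN-style overview tables are tallied into per-genome glycoside-hydrolase
family counts (subfamilies like GH5_25 collapse to their family), then
summed per polymer (agar, cellulose, chitin, pectin, xylan) through a
configurable family → polymer map.  Families absent from the map land in an
"unmapped" bucket rather than being dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
import yaml

from .model import ValidationError

logger = logging.getLogger(__name__)

# CAZy family token: class prefix + family number, optional subfamily and
# coordinate decorations, e.g. "GH5_25", "GH18(23-214)", "CBM50".
FAMILY_RE = re.compile(r"^([A-Z]{2,3}\d+)(?:_\d+)?(?:\(.*\))?$")


@dataclass
class CazymeCounts:
    genome_id: str
    counts: dict = field(default_factory=dict)  # family -> count

    def __post_init__(self) -> None:
        for fam, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"{self.genome_id}: negative count for {fam}")

    def merged_with(self, other: "CazymeCounts", genome_id: str = None) -> "CazymeCounts":
        out = dict(self.counts)
        for fam, n in other.counts.items():
            out[fam] = out.get(fam, 0) + n
        return CazymeCounts(genome_id or self.genome_id, out)


def parse_family_token(token: str) -> str:
    """Collapse a dbCAN family token to its family (GH5_25 → GH5)."""
    token = token.strip()
    m = FAMILY_RE.match(token)
    if not m:
        raise ValueError(f"unparseable CAZyme family token {token!r}")
    return m.group(1)


def read_dbcan_overview(path, genome_id: str) -> CazymeCounts:
    """Tally a dbCAN "overview.txt" dialect into per-family counts.

    The first column is the gene id; family assignments are read from the
    HMMER column when the header names one, otherwise from the second
    column.  Multiple families on one gene ("GH18+CBM5") each count once.
    Unparseable tokens are skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected at least two columns")
    col = "HMMER" if "HMMER" in df.columns else df.columns[1]
    counts: dict = {}
    for token_field in df[col]:
        if not token_field or token_field in ("-", "N"):
            continue
        for token in token_field.split("+"):
            if not token.strip():
                continue
            try:
                fam = parse_family_token(token)
            except ValueError:
                logger.warning("%s: skipping unparseable family token %r", path, token)
                continue
            counts[fam] = counts.get(fam, 0) + 1
    return CazymeCounts(genome_id, counts)


def load_polymer_map(path) -> dict:
    """polymer → set of families, from YAML ({polymers: {chitin: [GH18, ...]}})."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {str(p): set(map(str, fams)) for p, fams in raw.get("polymers", {}).items()}


def polymer_profile(counts: CazymeCounts, polymer_map: dict) -> dict:
    """Per-polymer gene totals; zero rows retained, unmapped families reported.

    Returns {"totals": {polymer: n, ..., "unmapped": n},
             "matrix": DataFrame(family × polymer counts)}.
    """
    mapped = {fam for fams in polymer_map.values() for fam in fams}
    totals = {}
    rows = []
    for polymer in sorted(polymer_map):
        fams = polymer_map[polymer]
        total = 0
        for fam in sorted(fams):
            n = counts.counts.get(fam, 0)
            total += n
            rows.append({"family": fam, "polymer": polymer, "count": n})
    # recompute totals cleanly per polymer
    totals = {
        polymer: sum(counts.counts.get(f, 0) for f in fams)
        for polymer, fams in polymer_map.items()
    }
    unmapped = {f: n for f, n in counts.counts.items() if f not in mapped}
    totals["unmapped"] = sum(unmapped.values())
    for fam, n in sorted(unmapped.items()):
        rows.append({"family": fam, "polymer": "unmapped", "count": n})
    matrix = pd.DataFrame(rows, columns=["family", "polymer", "count"])
    return {"totals": totals, "matrix": matrix}


def profile_to_long(genome_profiles: dict) -> pd.DataFrame:
    """Long heatmap export over genomes: genome, family, polymer, count."""
    frames = []
    for gid, prof in genome_profiles.items():
        df = prof["matrix"].copy()
        df.insert(0, "genome", gid)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["genome", "family", "polymer", "count"])
    return pd.concat(frames, ignore_index=True)
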