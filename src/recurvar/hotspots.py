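"""Protein-coordinate mutational hotspots.

Parses HGVS ``p.`` protein-change strings (one- or three-letter amino-acid
codes), maps retained observations onto protein coordinates, and builds
per-gene lollipop tracks: recurrence counts per residue position across the
cohort. Positions beyond the registry protein length (transcript-isoform
mismatches) are quarantined with a warning instead of being silently
clipped or dropped.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from Bio.Data.IUPACData import protein_letters_3to1_extended

from .model import GeneRegistry

_THREE_TO_ONE = {k.capitalize(): v for k, v in protein_letters_3to1_extended.items()}
_THREE_TO_ONE["Ter"] = "*"

_AA1 = "ACDEFGHIKLMNPQRSTVWY"
# one-letter dialect: X123Y, X123*, X123fs, *123Y
_RE_ONE = re.compile(rf"^([{_AA1}*])(\d+)(fs|ext|del(?:ins[A-Za-z*]+)?|dup|[{_AA1}*])(?:\*?\d*)?$")
# three-letter dialect: Arg123Cys, Arg123Ter, Lys469fs
_RE_THREE = re.compile(r"^([A-Z][a-z]{2})(\d+)(fs|ext|del(?:ins[A-Za-z]+)?|dup|Ter|[A-Z][a-z]{2})(?:\*?\d*)?$")


class HgvsParseError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinChange:
    gene: Optional[str]
    position: int
    ref_aa: Optional[str]
    alt_aa: str          # one-letter code, "*" (stop), "fs", "del", "dup", "ext"
    kind: str            # missense | nonsense | stoploss | frameshift | other

    def __post_init__(self):
        if self.position < 1:
            raise HgvsParseError(f"protein position must be >= 1, got {self.position}")


def _classify(ref_aa: Optional[str], alt_aa: str) -> str:
    if alt_aa == "fs":
        return "frameshift"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stoploss"
    if len(alt_aa) == 1 and alt_aa in _AA1 and ref_aa is not None and ref_aa in _AA1:
        return "missense"
    return "other"


def parse_protein_change(hgvs_p: str, gene: Optional[str] = None) -> ProteinChange:
    """Parse an HGVS protein-change string into normalized one-letter form.

    Accepts an optional ``p.`` prefix, one- or three-letter codes, and
    truncates frameshift suffixes (``fs*12`` -> ``fs``). Multi-residue
    deletions/delins report the first affected residue.
    """
    s = hgvs_p.strip()
    if s.startswith("p."):
        s = s[2:]
    s = s.strip("()")
    if not s:
        raise HgvsParseError(f"empty protein change {hgvs_p!r}")
    # multi-residue span (e.g. Arg123_Gly125del): keep the first residue part
    if "_" in s:
        first, rest = s.split("_", 1)
        suffix = "del" if "del" in rest else ("dup" if "dup" in rest else "del")
        s = first + suffix

    m = _RE_THREE.match(s)
    if m:
        ref3, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if ref3 not in _THREE_TO_ONE:
            raise HgvsParseError(f"unknown amino acid {ref3!r} in {hgvs_p!r}")
        ref_aa = _THREE_TO_ONE[ref3]
        if alt in _THREE_TO_ONE:
            alt_aa = _THREE_TO_ONE[alt]
        elif alt.startswith("fs"):
            alt_aa = "fs"
        elif alt.startswith(("del", "dup", "ext")):
            alt_aa = alt[:3]
        else:
            raise HgvsParseError(f"cannot parse alternate residue in {hgvs_p!r}")
        kind = _classify(ref_aa, alt_aa)
        return ProteinChange(gene, pos, ref_aa, alt_aa, kind)

    m = _RE_ONE.match(s)
    if m:
        ref_aa, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if alt.startswith("fs"):
            alt_aa = "fs"
        elif alt.startswith("del"):
            alt_aa = "del"
        elif alt.startswith(("dup", "ext")):
            alt_aa = alt[:3]
        else:
            alt_aa = alt
        kind = _classify(ref_aa, alt_aa)
        return ProteinChange(gene, pos, ref_aa, alt_aa, kind)

    raise HgvsParseError(f"cannot parse protein change {hgvs_p!r}")


@dataclass
class LollipopTrack:
    gene: str
    protein_length: int
    points: pd.DataFrame          # position, count, per-kind breakdown columns
    annotations: list             # top-k (position, count) labels
    unmapped: int = 0             # observations with missing/unparseable HGVS
    quarantined: list = field(default_factory=list)  # (position, count) beyond protein length


def lollipop_track(gene: str, retained: pd.DataFrame, registry: GeneRegistry,
                   top_k: int = 3, distinct_patients: bool = False) -> LollipopTrack:
    """Per-residue recurrence track for one gene.

    Counts (patient, variant) observations per position by default, so two
    distinct substitutions at one residue sum there; set
    ``distinct_patients`` to count each patient once per position instead.
    """
    if gene not in registry:
        raise KeyError(f"gene {gene!r} absent from registry")
    plen = registry.protein_length(gene)
    sub = retained[retained["gene"] == gene]
    unmapped = 0
    recs = []
    for row in sub.itertuples(index=False):
        hgvs = getattr(row, "hgvs_p", "") or ""
        if not hgvs:
            unmapped += 1
            continue
        try:
            change = parse_protein_change(hgvs, gene=gene)
        except HgvsParseError:
            unmapped += 1
            continue
        recs.append({"position": change.position, "kind": change.kind,
                     "patient_id": row.patient_id})
    if recs:
        mapped = pd.DataFrame(recs)
        if distinct_patients:
            mapped = mapped.drop_duplicates(["position", "patient_id"])
        counts = mapped.groupby("position").size().rename("count")
        kinds = mapped.groupby(["position", "kind"]).size().unstack(fill_value=0)
        points = counts.to_frame().join(kinds).reset_index().sort_values("position").reset_index(drop=True)
    else:
        points = pd.DataFrame(columns=["position", "count"])
    over = points[points["position"] > plen] if len(points) else points
    quarantined = list(zip(over["position"].tolist(), over["count"].tolist())) if len(over) else []
    if quarantined:
        warnings.warn(
            f"{gene}: {len(quarantined)} position(s) beyond protein length {plen} quarantined",
            stacklevel=2,
        )
        points = points[points["position"] <= plen].reset_index(drop=True)
    top = points.sort_values(["count", "position"], ascending=[False, True]).head(top_k)
    annotations = list(zip(top["position"].tolist(), top["count"].tolist()))
    return LollipopTrack(gene=gene, protein_length=plen, points=points,
                         annotations=annotations, unmapped=unmapped,
                         quarantined=quarantined)
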