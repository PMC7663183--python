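"""IMGT-based substructure annotation of Fab heavy/light chains.

A Fab is decomposed into 28 substructures: per variable domain 3 CDRs and
4 framework regions (IMGT delimitations: CDR1 27–38, CDR2 56–65, CDR3
105–117), and per constant domain the 7 beta strands A–G.

Variable domains are numbered with an anchor-plus-gap-rule algorithm: the
four conserved residues of the IMGT unique numbering (Cys23, Trp41,
Cys104, Phe/Trp118) are located by scanning windows around their expected
offsets, framework stretches are aligned onto their fixed position ranges,
and loop residues are gapped middle-out. This is deliberately simpler
than a profile alignment: FR2 and FR3 are assumed indel-free (FR3 carries
all 39 positions 66–104), which holds for the packaged germline-like
frameworks and for most IgG1-Kappa variable domains.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from . import germline
from .errors import AnchorNotFound, LengthMismatch, LengthOutOfRange
from .tables import validate_sequence

V_LENGTH_BOUNDS = (90, 140)

_CHAIN_PREFIX = {"heavy": "H", "kappa": "L"}


@dataclass(frozen=True)
class ChainSequence:
    """One Fab chain: V domain followed by a constant domain.

    ``v_domain_end`` is the 0-based exclusive index separating the V
    domain from the constant domain.
    """

    chain_id: str  # "heavy" | "light"
    residues: str
    v_domain_end: int

    def __post_init__(self):
        if self.chain_id not in ("heavy", "light"):
            raise ValueError(f"chain_id must be heavy/light, got {self.chain_id!r}")
        object.__setattr__(self, "residues", validate_sequence(self.residues))
        if not 0 < self.v_domain_end < len(self.residues):
            raise ValueError("v_domain_end outside (0, length)")

    @property
    def v_domain(self) -> str:
        return self.residues[: self.v_domain_end]

    @property
    def c_domain(self) -> str:
        return self.residues[self.v_domain_end:]


@dataclass(frozen=True)
class RegionAnnotation:
    """A named substructure on one chain; 0-based half-open coordinates."""

    name: str
    start: int
    end: int
    chain_id: str

    def __post_init__(self):
        # start == end marks an empty region (possible for a short CDR);
        # descriptor modules emit zeros for it to keep matrices rectangular.
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start must be <= end")

    def sequence(self, chain: ChainSequence) -> str:
        return chain.residues[self.start: self.end]


@dataclass
class FabAnnotation:
    """All 28 substructures of a Fab plus the located conserved anchors."""

    heavy: ChainSequence
    light: ChainSequence
    regions: list[RegionAnnotation]
    anchors: dict[str, int] = field(default_factory=dict)

    def regions_for(self, chain_id: str) -> list[RegionAnnotation]:
        return [r for r in self.regions if r.chain_id == chain_id]

    def variable_regions(self) -> list[RegionAnnotation]:
        return [r for r in self.regions if not r.name.startswith("strand")]

    def constant_regions(self) -> list[RegionAnnotation]:
        return [r for r in self.regions if r.name.startswith("strand")]

    def chain(self, chain_id: str) -> ChainSequence:
        return self.heavy if chain_id == "heavy" else self.light

    def region_sequence(self, region: RegionAnnotation) -> str:
        return region.sequence(self.chain(region.chain_id))


@dataclass
class ImgtNumbering:
    """Assignment of residues to IMGT positions.

    ``positions`` maps position labels ("1".."128", insertions like
    "111.1") to 0-based residue indices; ``segments`` holds the absolute
    half-open index range of each region of the domain.
    """

    chain_kind: str
    positions: dict[str, int]
    segments: dict[str, tuple[int, int]]


def _find_anchor(seq: str, pattern: str, lo: int, hi: int, name: str) -> int:
    window = seq[max(lo, 0): hi]
    m = re.search(pattern, window)
    if m is None:
        raise AnchorNotFound(f"{name} not found in window [{lo}, {hi})")
    return max(lo, 0) + m.start()


def _middle_out(labels: list[str], indices: range) -> dict[str, int]:
    """IMGT loop gap rule: fill positions from both ends toward the middle."""
    n = len(indices)
    n_front = (n + 1) // 2
    out = {}
    for k in range(n_front):
        out[labels[k]] = indices[k]
    for k in range(n - n_front):
        out[labels[len(labels) - 1 - k]] = indices[n - 1 - k]
    return out


def _cdr3_labels(n: int) -> list[str]:
    """Ordered IMGT position labels for a CDR3 of n residues.

    Up to 13 residues the base positions 105–117 are filled middle-out;
    longer loops receive insertions 111.1, 112.1, ... between 111 and 112
    (111.x ascending then 112.x descending, per the IMGT insertion rule).
    """
    base = [str(p) for p in range(105, 118)]
    if n <= 13:
        filled = _middle_out(base, range(n))
        return [lab for lab in base if lab in filled]
    extra = n - 13
    ins_111 = [f"111.{k}" for k in range(1, (extra + 1) // 2 + 1)]
    ins_112 = [f"112.{k}" for k in range(extra // 2, 0, -1)]
    return base[:7] + ins_111 + ins_112 + base[7:]


def number_v_domain(seq: str, chain_kind: str) -> ImgtNumbering:
    """Assign IMGT unique-numbering positions 1–128 to a V-domain sequence.

    Raises :class:`AnchorNotFound` when a conserved anchor cannot be
    located and :class:`LengthOutOfRange` for implausible lengths.
    """
    if chain_kind not in _CHAIN_PREFIX:
        raise ValueError(f"chain_kind must be heavy/kappa, got {chain_kind!r}")
    seq = validate_sequence(seq)
    if not V_LENGTH_BOUNDS[0] <= len(seq) <= V_LENGTH_BOUNDS[1]:
        raise LengthOutOfRange(
            f"V-domain length {len(seq)} outside {V_LENGTH_BOUNDS}")

    i1 = _find_anchor(seq, "C", 18, 26, "Cys23")
    i2 = _find_anchor(seq, "W", i1 + 6, i1 + 20, "Trp41")
    i3 = _find_anchor(seq, "C", i2 + 48, i2 + 66, "Cys104")
    # J anchor: prefer the canonical [FW]-G-X-G motif, fall back to bare F/W.
    try:
        i4 = _find_anchor(seq, "[FW]G.G", i3 + 2, i3 + 30, "PheTrp118")
    except AnchorNotFound:
        i4 = _find_anchor(seq, "[FW]", i3 + 2, i3 + 30, "PheTrp118")

    positions: dict[str, int] = {}
    segments: dict[str, tuple[int, int]] = {}

    # FR1: positions 1-26, end-aligned so the conserved Cys sits at 23.
    n_fr1 = i1 + 4
    if n_fr1 > 26:
        raise LengthOutOfRange(f"FR1 has {n_fr1} residues (max 26)")
    for k in range(n_fr1):
        positions[str(26 - (n_fr1 - 1 - k))] = k
    segments["FR1"] = (0, n_fr1)

    # CDR1: positions 27-38, gapped middle-out.
    c1_lo, c1_hi = n_fr1, i2 - 2
    n_cdr1 = c1_hi - c1_lo
    if not 0 <= n_cdr1 <= 12:
        raise LengthOutOfRange(f"CDR1 has {n_cdr1} residues (0-12 allowed)")
    positions.update(_middle_out([str(p) for p in range(27, 39)],
                                 range(c1_lo, c1_hi)))
    segments["CDR1"] = (c1_lo, c1_hi)

    # FR2: positions 39-55, assumed indel-free (Trp41 two in).
    if i2 + 15 > len(seq):
        raise AnchorNotFound("sequence truncated inside FR2")
    for k in range(17):
        positions[str(39 + k)] = i2 - 2 + k
    segments["FR2"] = (i2 - 2, i2 + 15)

    # CDR2 (56-65) and FR3 (66-104): FR3 assumed gapless at 39 residues.
    stretch = i3 + 1 - (i2 + 15)
    n_cdr2 = stretch - 39
    if n_cdr2 > 10:
        raise LengthOutOfRange(f"CDR2 has {n_cdr2} residues (max 10)")
    if n_cdr2 < 0:
        n_cdr2 = 0
    c2_lo = i2 + 15
    positions.update(_middle_out([str(p) for p in range(56, 66)],
                                 range(c2_lo, c2_lo + n_cdr2)))
    segments["CDR2"] = (c2_lo, c2_lo + n_cdr2)
    fr3_lo = c2_lo + n_cdr2
    n_fr3 = i3 + 1 - fr3_lo
    for k in range(n_fr3):
        positions[str(104 - (n_fr3 - 1 - k))] = fr3_lo + k
    segments["FR3"] = (fr3_lo, i3 + 1)

    # CDR3: positions 105-117 (+ insertions), gapped middle-out.
    n_cdr3 = i4 - (i3 + 1)
    for lab, k in zip(_cdr3_labels(n_cdr3), range(i3 + 1, i4)):
        positions[lab] = k
    segments["CDR3"] = (i3 + 1, i4)

    # FR4: positions 118-128.
    n_fr4 = len(seq) - i4
    if n_fr4 > 11:
        raise LengthOutOfRange(f"FR4 has {n_fr4} residues (max 11)")
    for k in range(n_fr4):
        positions[str(118 + k)] = i4 + k
    segments["FR4"] = (i4, len(seq))

    # Verify the anchors map to the required identities.
    for name, pos, allowed in (("Cys23", "23", "C"), ("Trp41", "41", "W"),
                               ("Cys104", "104", "C"), ("PheTrp118", "118", "FW")):
        idx = positions.get(pos)
        if idx is None or seq[idx] not in allowed:
            raise AnchorNotFound(f"{name} does not map to {allowed}")

    return ImgtNumbering(chain_kind=chain_kind, positions=positions,
                         segments=segments)


def extract_v_regions(numbering: ImgtNumbering) -> list[RegionAnnotation]:
    """The 7 variable-domain regions (FR1..FR4, CDR1..3) from a numbering.

    Regions tile the domain: concatenating their sequences reproduces the
    input exactly. A CDR absent after numbering becomes a zero-length
    region (start == end).
    """
    chain_letter = _CHAIN_PREFIX[numbering.chain_kind]
    chain_id = "heavy" if numbering.chain_kind == "heavy" else "light"
    out = []
    for region in ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"):
        lo, hi = numbering.segments[region]
        kind, num = region[:-1], region[-1]
        out.append(RegionAnnotation(name=f"{kind}-{chain_letter}{num}",
                                    start=lo, end=hi, chain_id=chain_id))
    return out


def extract_c_strands(seq: str, domain_kind: str,
                      offset: int = 0) -> list[RegionAnnotation]:
    """The 7 beta strands (A–G) of a constant domain.

    ``seq`` must match the packaged allele template length (IGHG1*01 CH1
    or IGLK1*01 CL); ``offset`` shifts coordinates onto full-chain indices.
    """
    templates = {"CH1": germline.IGHG1_CH1, "CL": germline.IGLK1_CL}
    if domain_kind not in templates:
        raise ValueError(f"domain_kind must be CH1/CL, got {domain_kind!r}")
    seq = validate_sequence(seq)
    template = templates[domain_kind]
    if len(seq) != len(template):
        raise LengthMismatch(
            f"{domain_kind} length {len(seq)} != allele template {len(template)}")
    chain_id = "heavy" if domain_kind == "CH1" else "light"
    return [
        RegionAnnotation(name=f"strand-{domain_kind}-{strand}",
                         start=offset + lo, end=offset + hi, chain_id=chain_id)
        for strand, (lo, hi) in germline.C_STRAND_BOUNDS[domain_kind].items()
    ]


def annotate_fab(heavy: ChainSequence, light: ChainSequence) -> FabAnnotation:
    """Annotate a Fab into its 28 substructures.

    Deterministic: identical input yields identical annotation.
    """
    num_h = number_v_domain(heavy.v_domain, "heavy")
    num_l = number_v_domain(light.v_domain, "kappa")

    regions = []
    for num, chain in ((num_h, heavy), (num_l, light)):
        regions.extend(extract_v_regions(num))
    regions.extend(extract_c_strands(heavy.c_domain, "CH1",
                                     offset=heavy.v_domain_end))
    regions.extend(extract_c_strands(light.c_domain, "CL",
                                     offset=light.v_domain_end))

    anchors = {}
    for prefix, num in (("H", num_h), ("L", num_l)):
        for name, pos in germline.ANCHOR_POSITIONS.items():
            anchors[f"{prefix}.{name}"] = num.positions[str(pos)]
    return FabAnnotation(heavy=heavy, light=light, regions=regions,
                         anchors=anchors)


# --- interchange ----------------------------------------------------------

def annotations_to_frame(fabs: dict[str, FabAnnotation]) -> pd.DataFrame:
    """Tabulate annotations (1-based inclusive coordinates for output)."""
    rows = []
    for sample, fab in fabs.items():
        for region in fab.regions:
            rows.append({
                "sample": sample, "chain": region.chain_id,
                "region": region.name, "start": region.start + 1,
                "end": region.end, "sequence": fab.region_sequence(region),
            })
    return pd.DataFrame(rows)


def write_annotations(fabs: dict[str, FabAnnotation], path) -> None:
    annotations_to_frame(fabs).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Read the TSV interchange table (coordinates stay 1-based inclusive)."""
    return pd.read_csv(path, sep="\t")


def frame_to_regions(frame: pd.DataFrame, sample: str) -> list[RegionAnnotation]:
    """Rebuild RegionAnnotations (0-based half-open) for one sample."""
    sub = frame[frame["sample"] == sample]
    return [RegionAnnotation(name=row.region, start=int(row.start) - 1,
                             end=int(row.end), chain_id=row.chain)
            for row in sub.itertuples()]


def read_fasta_pairs(heavy_path, light_path) -> dict[str, tuple[str, str]]:
    """Read multi-record FASTA chain files; ids parsed as "<sample>_<H|L>"."""
    import biotite.sequence.io.fasta as fasta

    def load(path, suffix):
        out = {}
        for header, seq in fasta.FastaFile.read(str(path)).items():
            name = header.split()[0]
            if not name.endswith(f"_{suffix}"):
                raise ValueError(f"record {name!r} does not end with _{suffix}")
            out[name[: -2]] = str(seq).strip().upper()
        return out

    heavies = load(heavy_path, "H")
    lights = load(light_path, "L")
    if set(heavies) != set(lights):
        raise ValueError("heavy/light FASTA files list different samples")
    return {s: (heavies[s], lights[s]) for s in sorted(heavies)}


def chain_from_sequence(chain_id: str, residues: str,
                        v_domain_end: int | None = None) -> ChainSequence:
    """Build a ChainSequence, inferring the V/C boundary from the packaged
    constant-domain allele length when not given."""
    residues = validate_sequence(residues)
    if v_domain_end is None:
        const = germline.IGHG1_CH1 if chain_id == "heavy" else germline.IGLK1_CL
        v_domain_end = len(residues) - len(const)
    return ChainSequence(chain_id=chain_id, residues=residues,
                        v_domain_end=v_domain_end)
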