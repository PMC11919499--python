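"""Codon-level ORF handling: parsing, elongation-rate tables, slow-codon-window
variant design, and siRNA target/seed-site scanning.

Conventions
-----------
All sequences are stored as uppercase DNA (``U`` is converted to ``T`` on
input).  Codon positions and nucleotide positions are 1-based; intervals are
fully closed, so a 10-codon window starting at codon 64 spans codons 64-73
inclusive.  A terminal stop codon is trimmed from the ORF on load (and the
trim recorded on the :class:`Orf`); windows never touch the stop.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "Orf",
    "ElongationRateTable",
    "SlowWindowVariant",
    "SirnaSite",
    "SeedSafetyReport",
    "load_orf",
    "load_guides",
    "default_rate_table",
    "slowest_synonym",
    "generate_slow_window_variants",
    "map_sirna_sites",
    "scan_seed_matches",
    "seed_quartile_counts",
    "check_variant_seed_safety",
    "write_variants_fasta",
    "write_site_report",
    "packaged_data",
]

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))

#: amino acid -> sorted tuple of synonymous codons (standard genetic code)
SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    SYNONYMS.setdefault(_aa, ())
    SYNONYMS[_aa] = tuple(sorted(SYNONYMS[_aa] + (_codon,)))

# Human codon usage, frequency per thousand codons (GenBank aggregate).
# Used to derive the default elongation-rate table: rate proportional to
# relative synonymous codon usage (RSCU), which by construction has mean 1
# over the 61 sense codons.  This is a stand-in parameterization that
# preserves the ordinal optimal/non-optimal structure; any user TSV with the
# same shape is accepted.
HUMAN_CODON_FREQ_PER_1000: dict[str, float] = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "AGT": 12.1, "AGC": 19.5,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3,
    "CAT": 10.9, "CAC": 15.1,
    "CAA": 12.3, "CAG": 34.2,
    "AAT": 17.0, "AAC": 19.1,
    "AAA": 24.4, "AAG": 31.9,
    "GAT": 21.8, "GAC": 25.1,
    "GAA": 29.0, "GAG": 39.6,
    "TGT": 10.6, "TGC": 12.6, "TGG": 13.2,
    "CGT": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGA": 12.2, "AGG": 12.0,
    "GGT": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}


def _normalize_seq(seq: str) -> str:
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return s


def translate_codons(codons: tuple[str, ...]) -> str:
    return str(Seq("".join(codons)).translate())


@dataclass(frozen=True)
class Orf:
    """A coding sequence as an ordered codon list.

    ``stop_trimmed`` records whether a terminal stop codon was removed when
    the record was read from FASTA.
    """

    id: str
    codons: tuple[str, ...]
    stop_trimmed: bool = False

    def __post_init__(self) -> None:
        for i, c in enumerate(self.codons, start=1):
            if len(c) != 3 or set(c) - set("ACGT"):
                raise ValueError(f"codon {i} ({c!r}) is not a DNA triplet")
            if c in STOP_CODONS:
                raise ValueError(f"internal stop at codon {i}")

    @property
    def length(self) -> int:
        """Codon count L."""
        return len(self.codons)

    @property
    def nt(self) -> str:
        return "".join(self.codons)

    @property
    def protein(self) -> str:
        return translate_codons(self.codons)

    @classmethod
    def from_nt(cls, id: str, seq: str, trim_stop: bool = True) -> "Orf":
        s = _normalize_seq(seq)
        if len(s) % 3:
            raise ValueError(
                f"record {id!r}: length {len(s)} not divisible by 3"
            )
        codons = tuple(s[i : i + 3] for i in range(0, len(s), 3))
        trimmed = False
        if trim_stop and codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
            trimmed = True
        return cls(id=id, codons=codons, stop_trimmed=trimmed)


@dataclass(frozen=True)
class ElongationRateTable:
    """Per-codon elongation rates ``omega`` (events per unit time).

    All 61 sense codons must be present with positive rates; stop codons are
    rejected.  The default table ships on an arbitrary mean-1 scale; the
    simulator applies its own time-unit scale factor.
    """

    rates: dict[str, float]
    source: str = "user"

    def __post_init__(self) -> None:
        keys = set(self.rates)
        missing = set(SENSE_CODONS) - keys
        if missing:
            raise ValueError(f"rate table missing codons: {sorted(missing)[:5]}...")
        stops = keys & STOP_CODONS
        if stops:
            raise ValueError(f"rate table contains stop codons: {sorted(stops)}")
        for c, w in self.rates.items():
            if not (w > 0 and math.isfinite(w)):
                raise ValueError(f"rate for {c} must be finite and > 0, got {w}")

    def __getitem__(self, codon: str) -> float:
        return self.rates[codon]

    def omega(self, orf: Orf) -> list[float]:
        """Per-codon rates along an ORF, in reading-frame order."""
        return [self.rates[c] for c in orf.codons]

    @classmethod
    def from_tsv(cls, path: str | Path, source: str | None = None) -> "ElongationRateTable":
        df = pd.read_csv(path, sep="\t")
        if not {"codon", "rate"} <= set(df.columns):
            raise ValueError("rate table TSV needs header columns 'codon' and 'rate'")
        rates = {
            _normalize_seq(c): float(r) for c, r in zip(df["codon"], df["rate"])
        }
        return cls(rates=rates, source=source or str(path))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"codon": list(self.rates), "rate": list(self.rates.values())}
        ).to_csv(path, sep="\t", index=False)


def default_rate_table() -> ElongationRateTable:
    """Default elongation-rate table from human codon usage.

    Rate of codon c = RSCU(c) = usage(c) / mean usage of its synonym family,
    rescaled so the mean over all 61 sense codons is exactly 1.0.
    """
    rates: dict[str, float] = {}
    for aa, codons in SYNONYMS.items():
        fam_mean = sum(HUMAN_CODON_FREQ_PER_1000[c] for c in codons) / len(codons)
        for c in codons:
            rates[c] = HUMAN_CODON_FREQ_PER_1000[c] / fam_mean
    grand = sum(rates.values()) / len(rates)
    rates = {c: w / grand for c, w in rates.items()}
    return ElongationRateTable(rates=rates, source="human-RSCU")


@dataclass(frozen=True)
class SlowWindowVariant:
    """An ORF with one contiguous window of synonymous de-optimized codons."""

    parent: str
    window_start: int  # 1-based codon index of the first mutated position
    window_len: int
    codons: tuple[str, ...]

    @property
    def id(self) -> str:
        return f"{self.parent}_win{self.window_start:03d}"

    @property
    def window_end(self) -> int:
        return self.window_start + self.window_len - 1

    def to_orf(self) -> Orf:
        return Orf(id=self.id, codons=self.codons)


@dataclass(frozen=True)
class SirnaSite:
    """A (full or seed) siRNA match on the sense strand of an ORF."""

    sirna_id: str
    start_nt: int  # 1-based position of the 5'-most matched target nucleotide
    match_len: int
    kind: str = "full"  # "full" | "seed"


@dataclass
class SeedSafetyReport:
    variant_id: str
    gained: list[SirnaSite] = field(default_factory=list)
    lost: list[SirnaSite] = field(default_factory=list)

    @property
    def no_full_site_gained(self) -> bool:
        return not any(s.kind == "full" for s in self.gained)


# ---------------------------------------------------------------------------
# I/O

def packaged_data(name: str) -> Path:
    """Path of a data file shipped with the package."""
    return Path(__file__).parent / "data" / name


def load_orf(path: str | Path, record_id: str | None = None) -> Orf:
    """Read one ORF from a FASTA file.

    A terminal stop codon is trimmed (recorded on the Orf); a non-multiple-
    of-3 length or an internal stop raises ``ValueError`` with the offending
    position.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValueError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    return Orf.from_nt(rec.id, str(rec.seq))


def load_guides(path: str | Path) -> dict[str, str]:
    """Read siRNA guide strands from FASTA; RNA alphabet is normalized."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = _normalize_seq(str(rec.seq))
    if not out:
        raise ValueError(f"no guide records in {path}")
    return out


def write_variants_fasta(
    variants: list[SlowWindowVariant], path: str | Path, parent: Orf | None = None
) -> None:
    with open(path, "w") as f:
        if parent is not None:
            f.write(f">{parent.id}\n{parent.nt}\n")
        for v in variants:
            f.write(f">{v.id} window={v.window_start}-{v.window_end}\n")
            f.write("".join(v.codons) + "\n")


def write_site_report(sites: list[SirnaSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sirna_id": s.sirna_id, "start_nt": s.start_nt,
             "match_len": s.match_len, "kind": s.kind}
            for s in sites
        ],
        columns=["sirna_id", "start_nt", "match_len", "kind"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant design

def slowest_synonym(codon: str, rates: ElongationRateTable) -> str:
    """The synonymous codon with minimal elongation rate.

    Returns the input unchanged when it is already the slowest or when the
    amino acid has a single codon (Met, Trp).  Ties break to the
    lexicographically smallest codon.
    """
    codon = _normalize_seq(codon)
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no synonym")
    aa = standard_dna_table.forward_table[codon]
    family = SYNONYMS[aa]
    best = min(family, key=lambda c: (rates[c], c))
    if rates[best] < rates[codon]:
        return best
    if rates[best] == rates[codon] and best < codon:
        return best
    return codon


def generate_slow_window_variants(
    orf: Orf, rates: ElongationRateTable, window_len: int = 10
) -> list[SlowWindowVariant]:
    """One variant per window placement: L - window_len + 1 variants.

    Within each window every codon is replaced by its slowest synonym; all
    positions outside the window are untouched, so every variant translates
    to the parent protein.
    """
    L = orf.length
    if window_len > L:
        raise ValueError(f"window_len {window_len} exceeds ORF length {L}")
    slow = [slowest_synonym(c, rates) for c in orf.codons]
    out = []
    for start in range(1, L - window_len + 2):
        codons = list(orf.codons)
        codons[start - 1 : start - 1 + window_len] = slow[start - 1 : start - 1 + window_len]
        out.append(
            SlowWindowVariant(
                parent=orf.id, window_start=start, window_len=window_len,
                codons=tuple(codons),
            )
        )
    return out


# ---------------------------------------------------------------------------
# siRNA site scanning

def _find_all(haystack: str, needle: str) -> list[int]:
    """1-based start positions of all (possibly overlapping) occurrences."""
    return [m.start() + 1 for m in re.finditer(f"(?={re.escape(needle)})", haystack)]


def map_sirna_sites(orf: Orf, guide: str, sirna_id: str = "siRNA") -> list[SirnaSite]:
    """Full target sites: positions where the ORF contains the exact
    reverse complement of the guide strand."""
    g = _normalize_seq(guide)
    if len(g) < 10:
        raise ValueError(f"guide too short ({len(g)} nt, need >= 10)")
    target = str(Seq(g).reverse_complement())
    return [
        SirnaSite(sirna_id=sirna_id, start_nt=p, match_len=len(g), kind="full")
        for p in _find_all(orf.nt, target)
    ]


def scan_seed_matches(
    orf: Orf, guide: str, sirna_id: str = "siRNA", seed_span: tuple[int, int] = (2, 8)
) -> list[SirnaSite]:
    """Seed-complementary regions on the ORF.

    The seed is guide positions ``seed_span`` (default 2-8, the minimal
    7-mer; perfect complementarity, no G:U wobble).  Since the seed sits at
    the guide 5' end, its complement occupies the 3' end of a full target
    site: a full site starting at s with length m implies a seed hit at
    ``s + m - seed_end - (seed_len - 1) + ...`` — concretely guide position
    k pairs with target nucleotide ``s + m - k``.  Seed hits that coincide
    with a full site are flagged ``kind="full"``.
    """
    g = _normalize_seq(guide)
    if len(g) < 10:
        raise ValueError(f"guide too short ({len(g)} nt, need >= 10)")
    lo, hi = seed_span
    seed = g[lo - 1 : hi]
    target = str(Seq(seed).reverse_complement())
    full_starts = {s.start_nt for s in map_sirna_sites(orf, g, sirna_id)}
    # guide position k pairs with target nt (site_start + site_len - k);
    # the seed complement therefore starts at site_start + len(g) - hi.
    seed_starts_from_full = {s + len(g) - hi for s in full_starts}
    return [
        SirnaSite(
            sirna_id=sirna_id, start_nt=p, match_len=len(target),
            kind="full" if p in seed_starts_from_full else "seed",
        )
        for p in _find_all(orf.nt, target)
    ]


def seed_quartile_counts(orf: Orf, guides: dict[str, str]) -> list[int]:
    """Seed-match counts per sequence quartile (5' to 3')."""
    n = 3 * orf.length
    edges = [1 + round(q * n / 4) for q in range(5)]
    counts = [0, 0, 0, 0]
    for gid, g in guides.items():
        for site in scan_seed_matches(orf, g, sirna_id=gid):
            for q in range(4):
                if edges[q] <= site.start_nt < edges[q + 1] or (
                    q == 3 and site.start_nt == n
                ):
                    counts[q] += 1
                    break
    return counts


def check_variant_seed_safety(
    variant: SlowWindowVariant, parent: Orf, guides: dict[str, str]
) -> SeedSafetyReport:
    """Seed/full sites gained or lost by the synonymous window relative to
    the parent ORF."""
    v_orf = variant.to_orf()
    report = SeedSafetyReport(variant_id=variant.id)
    for gid, g in guides.items():
        for finder in (map_sirna_sites, scan_seed_matches):
            before_sites = finder(parent, g, sirna_id=gid)
            after_sites = finder(v_orf, g, sirna_id=gid)
            before_keys = {(s.start_nt, s.match_len) for s in before_sites}
            after_keys = {(s.start_nt, s.match_len) for s in after_sites}
            report.gained.extend(
                s for s in after_sites if (s.start_nt, s.match_len) not in before_keys
            )
            report.lost.extend(
                s for s in before_sites if (s.start_nt, s.match_len) not in after_keys
            )
    return report
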