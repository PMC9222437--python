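"""Exon-3 haplotypes of the X-linked cone opsin genes (*OPN1LW*/*OPN1MW*).

A haplotype is the joint allele configuration at eight biallelic SNPs inside
opsin exon 3, written as an 8-nucleotide string in a fixed canonical SNP
order.  Five of the eight positions are non-synonymous and jointly determine
the amino acids at opsin protein positions 153, 171, 174, 178 and 180; the
other three are synonymous.  Two of the SNPs (rs5986963 and rs5986964) are in
near-complete association in *OPN1LW* genes and occur only in the joint
states (A,T) or (G,G), which is why the full minigene panel enumerates
2**6 * 2 = 128 haplotypes rather than 2**8 = 256.

The SNP panel (ids, positions, alleles, codon assignments) is shipped as a
packaged TSV so the same machinery applies to *OPN1MW* exon-3 haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from itertools import product

from .errors import ValidationError

__all__ = [
    "SnpDef",
    "ExonThreeHaplotype",
    "load_snp_panel",
    "parse_haplotype",
    "translate_haplotype",
    "enumerate_minigene_haplotypes",
    "allele_at",
    "CONSTRAINED_PAIR",
    "CONSTRAINED_JOINT_STATES",
]

NUCLEOTIDES = frozenset("ACGT")

#: SNPs that vary jointly, and the only joint allele states observed.
CONSTRAINED_PAIR = ("rs5986963", "rs5986964")
CONSTRAINED_JOINT_STATES = (("A", "T"), ("G", "G"))


@dataclass(frozen=True)
class SnpDef:
    """One SNP of the exon-3 panel.

    ``codon``/``aa1``/``aa2`` are ``None`` for synonymous positions.  The
    allele order (allele1, allele2) follows the published allele listings and
    is meaningful: per-SNP effect folds are reported as allele2 over allele1.
    """

    snp_id: str
    position: int  # 1-based position in the 8-character haplotype string
    allele1: str
    allele2: str
    codon: int | None = None
    aa1: str | None = None
    aa2: str | None = None
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise ValidationError(f"{self.snp_id}: alleles must differ")
        for a in (self.allele1, self.allele2):
            if a not in NUCLEOTIDES:
                raise ValidationError(f"{self.snp_id}: bad allele {a!r}")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele1, self.allele2)

    @property
    def is_coding(self) -> bool:
        return self.codon is not None

    def amino_acid(self, allele: str) -> str:
        if not self.is_coding:
            raise ValidationError(f"{self.snp_id} is synonymous")
        if allele == self.allele1:
            return self.aa1  # type: ignore[return-value]
        if allele == self.allele2:
            return self.aa2  # type: ignore[return-value]
        raise ValidationError(
            f"allele {allele!r} is not defined for {self.snp_id} "
            f"(expected {self.allele1} or {self.allele2})"
        )


@lru_cache(maxsize=None)
def load_snp_panel() -> tuple[SnpDef, ...]:
    """Load the canonical 8-SNP exon-3 panel from packaged data.

    Returns SNPs sorted by haplotype position (1..8).
    """
    text = (
        resources.files("opsinhap").joinpath("data/snp_panel.tsv").read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    defs = []
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        defs.append(
            SnpDef(
                snp_id=row["snp_id"],
                position=int(row["position"]),
                allele1=row["allele1"],
                allele2=row["allele2"],
                codon=None if row["codon"] == "." else int(row["codon"]),
                aa1=None if row["aa1"] == "." else row["aa1"],
                aa2=None if row["aa2"] == "." else row["aa2"],
                aliases=()
                if row["aliases"] == "."
                else tuple(row["aliases"].split(",")),
            )
        )
    defs.sort(key=lambda d: d.position)
    if len(defs) != 8:
        raise ValidationError("canonical panel must contain exactly 8 SNPs")
    return tuple(defs)


def _resolve_snp(snp_id: str, panel: tuple[SnpDef, ...]) -> SnpDef:
    for snp in panel:
        if snp.snp_id == snp_id or snp_id in snp.aliases:
            return snp
    known = ", ".join(s.snp_id for s in panel)
    raise ValidationError(f"unknown SNP id {snp_id!r} (panel: {known})")


@dataclass(frozen=True)
class ExonThreeHaplotype:
    """A validated 8-nucleotide exon-3 haplotype.

    ``off_panel`` lists 1-based positions whose allele is a real nucleotide
    but not one of the two defined panel alleles (possible only when parsed
    in lenient mode).
    """

    alleles: str
    off_panel: tuple[int, ...] = field(default=(), compare=False)

    def __str__(self) -> str:
        return self.alleles

    def __getitem__(self, position: int) -> str:
        """Allele at 1-based panel position."""
        return self.alleles[position - 1]


def parse_haplotype(
    text: str, strict: bool = True, panel: tuple[SnpDef, ...] | None = None
) -> ExonThreeHaplotype:
    """Parse an 8-character haplotype string (case-insensitive).

    In strict mode every allele must be one of the two defined alleles at its
    panel position; in lenient mode off-panel nucleotides are retained and
    flagged via :attr:`ExonThreeHaplotype.off_panel`.
    """
    panel = panel or load_snp_panel()
    s = str(text).strip().upper()
    if len(s) != len(panel):
        raise ValidationError(
            f"haplotype {text!r} has length {len(s)}, expected {len(panel)}"
        )
    bad = [c for c in s if c not in NUCLEOTIDES]
    if bad:
        raise ValidationError(f"haplotype {text!r}: non-nucleotide {bad[0]!r}")
    off = tuple(
        snp.position for snp in panel if s[snp.position - 1] not in snp.alleles
    )
    if off and strict:
        snp = panel[off[0] - 1]
        raise ValidationError(
            f"haplotype {s!r}: allele {s[off[0] - 1]!r} at position "
            f"{off[0]} is not an allele of {snp.snp_id} "
            f"(expected {snp.allele1} or {snp.allele2})"
        )
    return ExonThreeHaplotype(s, off)


def translate_haplotype(
    hap: ExonThreeHaplotype | str, panel: tuple[SnpDef, ...] | None = None
) -> str:
    """Translate a haplotype to its 5-residue amino-acid string.

    Residues correspond to opsin protein positions 153, 171, 174, 178 and
    180, in that order; synonymous panel positions are ignored.
    """
    panel = panel or load_snp_panel()
    if isinstance(hap, str):
        hap = parse_haplotype(hap, strict=False, panel=panel)
    residues = []
    for snp in panel:
        if not snp.is_coding:
            continue
        residues.append(snp.amino_acid(hap[snp.position]))
    return "".join(residues)


def enumerate_minigene_haplotypes(
    panel: tuple[SnpDef, ...] | None = None,
) -> list[ExonThreeHaplotype]:
    """Enumerate the 128-haplotype minigene design space.

    The six unconstrained SNPs vary freely over their two alleles; the
    (rs5986963, rs5986964) pair takes only its two observed joint states.
    Output is deduplicated and sorted lexicographically.
    """
    panel = panel or load_snp_panel()
    pair_pos = tuple(_resolve_snp(s, panel).position for s in CONSTRAINED_PAIR)
    free = [snp for snp in panel if snp.position not in pair_pos]
    out = set()
    for combo in product(*(snp.alleles for snp in free)):
        for state in CONSTRAINED_JOINT_STATES:
            alleles = [""] * len(panel)
            for snp, a in zip(free, combo):
                alleles[snp.position - 1] = a
            for pos, a in zip(pair_pos, state):
                alleles[pos - 1] = a
            out.add("".join(alleles))
    return [ExonThreeHaplotype(s) for s in sorted(out)]


def allele_at(
    hap: ExonThreeHaplotype | str,
    snp_id: str,
    panel: tuple[SnpDef, ...] | None = None,
) -> str:
    """Allele carried by ``hap`` at the SNP named ``snp_id`` (aliases OK)."""
    panel = panel or load_snp_panel()
    snp = _resolve_snp(snp_id, panel)
    if isinstance(hap, str):
        hap = parse_haplotype(hap, strict=False, panel=panel)
    return hap[snp.position]
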