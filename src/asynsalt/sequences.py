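"""Sequence-level titration model.

Per-site Henderson–Hasselbalch (HH) charges, net charge versus pH, the
isoelectric point and region charges for intrinsically disordered proteins.
α-Synuclein is the packaged example: 140 residues with a strongly asymmetric
charge distribution — a basic N-terminal region (residues 1–60), an almost
uncharged central NAC region (61–95) and a highly acidic C-terminal tail
(101–140).

The model is the textbook null model: every titratable group titrates
independently with an intrinsic pKa, so the mean charge of an acid is
``-1/(1 + 10**(pKa - pH))`` and of a base ``+1/(1 + 10**(pH - pKa))``.
Site–site electrostatic coupling (which shifts apparent pKa values in the real
protein) is deliberately absent here; it is handled by the constant-pH Monte
Carlo model in :mod:`asynsalt.mc`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_PKA_SET",
    "ProteinSequence",
    "TitratableSite",
    "ChargeProfile",
    "read_fasta",
    "load_asyn",
    "load_asyn_ctail",
    "titratable_sites",
    "site_mean_charge",
    "net_charge",
    "isoelectric_point",
    "charge_profile",
    "write_charge_table",
    "read_pka_config",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Intrinsic pKa values of titratable groups (side chains and free termini).
#: These are the common coarse-grained-model values; any mapping with the same
#: keys may be passed instead (e.g. a measured per-protein set).
DEFAULT_PKA_SET: dict[str, float] = {
    "D": 4.0,
    "E": 4.4,
    "H": 6.3,
    "Y": 9.6,
    "K": 10.4,
    "R": 12.0,
    "C": 10.8,
    "NTERM": 7.5,
    "CTERM": 3.6,
}

#: Residue types whose side chain is acidic (deprotonated form carries -1 e).
ACIDIC_RESIDUES = set("DEYC")
#: Residue types whose side chain is basic (protonated form carries +1 e).
BASIC_RESIDUES = set("HKR")


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter residue string plus terminal-group flags."""

    residues: str
    name: str = ""
    has_free_nterm: bool = True
    has_free_cterm: bool = True

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"non-standard amino-acid codes in {self.name!r}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, stop: int, name: str = "") -> "ProteinSequence":
        """1-based inclusive slice; the fragment gets blocked termini."""
        return ProteinSequence(
            self.residues[start - 1 : stop],
            name=name or f"{self.name}[{start}-{stop}]",
            has_free_nterm=False,
            has_free_cterm=False,
        )


@dataclass(frozen=True)
class TitratableSite:
    """A single titratable group.

    ``position`` is the 1-based residue index; 0 denotes the N-terminal amine
    and ``len(seq) + 1`` the C-terminal carboxyl.
    """

    position: int
    kind: str  # "acid" | "base"
    pka_intrinsic: float
    charge_protonated: int
    charge_deprotonated: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("acid", "base"):
            raise ValueError(f"kind must be 'acid' or 'base', got {self.kind!r}")
        expect = (0, -1) if self.kind == "acid" else (1, 0)
        if (self.charge_protonated, self.charge_deprotonated) != expect:
            raise ValueError(f"{self.kind} site must carry charges {expect}")
        if not 0.0 < self.pka_intrinsic < 14.0:
            raise ValueError("pKa_intrinsic must lie in (0, 14)")


@dataclass
class ChargeProfile:
    """Mean HH charges of a sequence at one pH."""

    pH: float
    site_charges: dict[int, float]
    net_charge: float
    region_charges: dict[str, float] = field(default_factory=dict)


def read_fasta(path: str | Path) -> ProteinSequence:
    """Read the first record of a FASTA file as a :class:`ProteinSequence`.

    Residues are uppercased; non-standard codes raise ``ValueError``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    rec = records[0]
    return ProteinSequence(str(rec.seq).upper(), name=rec.id)


def _packaged_fasta(name: str) -> ProteinSequence:
    ref = resources.files("asynsalt").joinpath("data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_fasta(path)


def load_asyn() -> ProteinSequence:
    """The packaged 140-residue human α-synuclein sequence."""
    return _packaged_fasta("asyn.fasta")


def load_asyn_ctail() -> ProteinSequence:
    """The packaged C-terminal tail (residues 101–140, length 40).

    The tail is a proteolytic-style fragment of the full sequence, so its
    N-terminus is still reported free here; when the tail is grafted to a
    surface in the MC model the anchor bead is made non-titratable instead.
    """
    seq = _packaged_fasta("asyn_ctail.fasta")
    return ProteinSequence(seq.residues, name=seq.name,
                           has_free_nterm=True, has_free_cterm=True)


def titratable_sites(
    seq: ProteinSequence, pka_set: Mapping[str, float] | None = None
) -> list[TitratableSite]:
    """Enumerate titratable groups: D/E/H/Y/K/R/C side chains plus free termini."""
    pka = dict(DEFAULT_PKA_SET if pka_set is None else pka_set)
    sites: list[TitratableSite] = []
    if seq.has_free_nterm:
        sites.append(
            TitratableSite(0, "base", pka["NTERM"], 1, 0, label="N-terminus")
        )
    for i, aa in enumerate(seq.residues, start=1):
        if aa in ACIDIC_RESIDUES:
            sites.append(TitratableSite(i, "acid", pka[aa], 0, -1, label=f"{aa}{i}"))
        elif aa in BASIC_RESIDUES:
            sites.append(TitratableSite(i, "base", pka[aa], 1, 0, label=f"{aa}{i}"))
    if seq.has_free_cterm:
        sites.append(
            TitratableSite(len(seq) + 1, "acid", pka["CTERM"], 0, -1,
                           label="C-terminus")
        )
    return sites


def site_mean_charge(site: TitratableSite, pH: float) -> float:
    """Mean HH charge of one site at the given pH (in e)."""
    if site.kind == "acid":
        return -1.0 / (1.0 + 10.0 ** (site.pka_intrinsic - pH))
    return 1.0 / (1.0 + 10.0 ** (pH - site.pka_intrinsic))


def net_charge(
    seq: ProteinSequence, pH: float, pka_set: Mapping[str, float] | None = None
) -> float:
    """Sum of HH mean charges over all titratable sites (in e).

    Strictly decreasing in pH, which makes the isoelectric point unique.
    """
    return sum(site_mean_charge(s, pH) for s in titratable_sites(seq, pka_set))


def isoelectric_point(
    seq: ProteinSequence,
    pka_set: Mapping[str, float] | None = None,
    tol: float = 1e-6,
) -> float:
    """pH at which the HH net charge vanishes, by bisection on (0, 14).

    Raises ``ValueError`` for sequences whose net charge does not change sign
    on (0, 14) (e.g. a polyacid with blocked termini has no pI).
    """
    lo, hi = 1e-9, 14.0 - 1e-9
    q_lo = net_charge(seq, lo, pka_set)
    q_hi = net_charge(seq, hi, pka_set)
    if q_lo <= 0.0 or q_hi >= 0.0:
        # net charge is monotone decreasing: need q(0) > 0 > q(14)
        raise ValueError("undefined pI: net charge has no zero on (0, 14)")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, pka_set)
        if abs(q) < tol:
            return mid
        if q > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


#: Region split used for α-synuclein: basic N-terminal region, uncharged NAC
#: core, acidic C-terminal tail.
ASYN_REGIONS: dict[str, tuple[int, int]] = {
    "nterm_1_60": (1, 60),
    "nac_61_95": (61, 95),
    "ctail_101_140": (101, 140),
}


def charge_profile(
    seq: ProteinSequence,
    pH: float,
    pka_set: Mapping[str, float] | None = None,
    regions: Mapping[str, tuple[int, int]] | None = None,
) -> ChargeProfile:
    """Per-site, net and per-region mean charges at one pH.

    Region sums include only side-chain sites whose residue index falls in the
    region; terminal groups are counted in a region only if the terminal
    residue itself lies inside it.
    """
    sites = titratable_sites(seq, pka_set)
    site_charges = {s.position: site_mean_charge(s, pH) for s in sites}
    total = sum(site_charges.values())
    region_charges: dict[str, float] = {}
    if regions:
        n = len(seq)
        for name, (start, stop) in regions.items():
            q = 0.0
            for s in sites:
                pos = s.position
                if pos == 0:
                    pos = 1  # N-terminal amine sits on residue 1
                elif pos == n + 1:
                    pos = n  # C-terminal carboxyl sits on the last residue
                if start <= pos <= stop:
                    q += site_charges[s.position]
            region_charges[name] = q
    return ChargeProfile(pH=pH, site_charges=site_charges,
                         net_charge=total, region_charges=region_charges)


def write_charge_table(
    seq: ProteinSequence,
    path: str | Path,
    ph_values: Sequence[float],
    pka_set: Mapping[str, float] | None = None,
    regions: Mapping[str, tuple[int, int]] | None = None,
) -> None:
    """Write a TSV of net and per-region charge versus pH."""
    regions = dict(regions or {})
    header = ["pH", "net_charge"] + list(regions)
    lines = ["\t".join(header)]
    for ph in ph_values:
        prof = charge_profile(seq, ph, pka_set, regions)
        row = [f"{ph:.3f}", f"{prof.net_charge:.6f}"]
        row += [f"{prof.region_charges[r]:.6f}" for r in regions]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pka_config(path: str | Path) -> dict[str, float]:
    """Read a pKa set from a plain-text ``KEY value`` / ``KEY=value`` file."""
    pka = dict(DEFAULT_PKA_SET)
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.replace("=", " ").partition(" ")
        key = key.strip().upper()
        if key not in pka:
            raise ValueError(f"unknown pKa key {key!r} in {path}")
        pka[key] = float(value)
    return pka
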