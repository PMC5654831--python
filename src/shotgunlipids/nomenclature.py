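"""Lipid shorthand nomenclature, acyl classification and the species database.

Species are named in the community shorthand ``<CLASS> <C>:<D>`` (sum
composition, total acyl carbons : total double bonds) or
``<CLASS> <C1>:<D1>/<C2>:<D2>`` (molecular species with resolved chains).
Sphingolipids (SM, CER) are named by their N-linked acyl only and carry the
implicit d18:1 sphingoid backbone.  Ether classes (PC-O, PE-O) have one
alkyl-linked chain in place of an ester-linked acyl.

The module also assembles elemental compositions and monoisotopic masses per
class formula, and enumerates the target database (sum species with
per-channel target m/z, plus candidate diacyl pairs used for molecular
resolution) that drives identification.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import pandas as pd

from .chem import (
    ADDUCT_MASS_SHIFT,
    ElementalComposition,
    PROTON_MASS,
    WATER,
)


class LipidNameError(ValueError):
    """Malformed shorthand name."""


class UnsupportedClassError(LipidNameError):
    """Class token not in the supported class set."""


class LevelError(ValueError):
    """Operation requires a different annotation level (sum vs molecular)."""


# ---------------------------------------------------------------------------
# scan channels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanChannel:
    """One acquisition channel: scan type, extract fraction, polarity."""

    scan_type: str          # e.g. "hg184", "nl141", "cls-TAG", "fa-16_0"
    extract: str = "total"  # "total" | "hydrolyzed"
    polarity: str = "+"

    @property
    def id(self) -> str:
        pol = "pos" if self.polarity == "+" else "neg"
        return f"{pol}_{self.scan_type}.{self.extract}"


def fa_channel(carbons: int, double_bonds: int) -> ScanChannel:
    """Negative-mode precursor-ion channel for one fatty acyl carboxylate."""
    return ScanChannel(f"fa-{carbons}_{double_bonds}", "total", "-")


CH_HG184 = ScanChannel("hg184", "total", "+")       # 184.1 phosphocholine scan
CH_HG184_HYD = ScanChannel("hg184", "hydrolyzed", "+")
CH_NL141 = ScanChannel("nl141", "total", "+")       # 141 PE head-group loss
CH_TAG = ScanChannel("cls-TAG", "total", "+")
CH_DAG = ScanChannel("cls-DAG", "total", "+")
CH_CE = ScanChannel("cls-CE", "total", "+")
CH_PS = ScanChannel("cls-PS", "total", "+")
CH_CER = ScanChannel("cls-CER", "hydrolyzed", "+")


# ---------------------------------------------------------------------------
# fatty acyls
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class FattyAcyl:
    """An acyl (ester/amide-linked) or alkyl (ether-linked) chain."""

    carbons: int
    double_bonds: int
    ether: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise LipidNameError(f"chain needs >= 2 carbons, got {self.carbons}")
        if not (0 <= self.double_bonds <= self.carbons // 2):
            raise LipidNameError(
                f"double bonds {self.double_bonds} out of range for "
                f"{self.carbons} carbons")

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    @property
    def free_acid_composition(self) -> ElementalComposition:
        """CnH(2n-2d)O2 for an acyl; fatty alcohol CnH(2n+2-2d)O for an alkyl."""
        c, d = self.carbons, self.double_bonds
        if self.ether:
            return ElementalComposition(C=c, H=2 * c + 2 - 2 * d, O=1)
        return ElementalComposition(C=c, H=2 * c - 2 * d, O=2)

    @property
    def carboxylate_mz(self) -> float:
        """m/z of the [FA-H]- carboxylate fragment (acyl chains only)."""
        if self.ether:
            raise LevelError("alkyl chains yield no carboxylate fragment")
        return self.free_acid_composition.monoisotopic_mass - PROTON_MASS


@dataclass(frozen=True)
class AcylClassification:
    is_pufa: bool
    omega_family: str  # "n-3" | "n-6" | "n-9" | "other" | "unassigned"


#: default omega-family lookup keyed by (carbons, double bonds).  Shorthand
#: cannot encode double-bond position, so family assignment is a convention:
#: the table below reflects the dominant mammalian isomer of each chain and
#: is configurable (22:5 in particular is ambiguous; n-3 DPA dominates in
#: muscle).
DEFAULT_OMEGA_TABLE: dict[tuple[int, int], str] = {
    (18, 2): "n-6",
    (18, 3): "n-3",
    (20, 3): "n-6",
    (20, 4): "n-6",
    (20, 5): "n-3",
    (22, 4): "n-6",
    (22, 5): "n-3",
    (22, 6): "n-3",
}


def classify_acyl(chain: FattyAcyl,
                  table: dict[tuple[int, int], str] | None = None,
                  ) -> AcylClassification:
    """PUFA flag (>= 2 double bonds) and omega family from the lookup table.

    ``is_pufa`` depends only on the double-bond count; the omega table can
    never change it.
    """
    if table is None:
        table = DEFAULT_OMEGA_TABLE
    family = table.get((chain.carbons, chain.double_bonds), "unassigned")
    return AcylClassification(is_pufa=chain.double_bonds >= 2,
                              omega_family=family)


# ---------------------------------------------------------------------------
# lipid classes
# ---------------------------------------------------------------------------

# head group + backbone residues (the part of the molecule chains attach to)
_GLYCEROL = ElementalComposition(C=3, H=8, O=3)
_GPC = ElementalComposition(C=8, H=20, N=1, O=6, P=1)   # glycerophosphocholine
_GPE = ElementalComposition(C=5, H=14, N=1, O=6, P=1)
_GPS = ElementalComposition(C=6, H=14, N=1, O=8, P=1)
_SPHINGOSINE = ElementalComposition(C=18, H=37, N=1, O=2)   # d18:1
_SM_RESIDUE = ElementalComposition(C=23, H=49, N=2, O=5, P=1)  # sphingosine+P-choline
_CHOLESTEROL = ElementalComposition(C=27, H=46, O=1)


@dataclass(frozen=True)
class LipidClass:
    """A quantified lipid class with its scaffold and acquisition channel."""

    name: str
    residue: ElementalComposition
    backbone_rule: str            # "glycerol" | "sphingoid-d18:1" | "sterol"
    n_chains: int
    ether: bool                   # one alkyl-linked chain (PC-O / PE-O)
    quant_channel: ScanChannel
    adduct: str                   # positive-mode precursor adduct
    always_sum_level: bool = False
    is_phospholipid: bool = False

    @property
    def extract_channel(self) -> str:
        return self.quant_channel.extract


def _cls(name, residue, backbone, n_chains, channel, adduct, *, ether=False,
         always_sum=False, pl=False) -> LipidClass:
    return LipidClass(name, residue, backbone, n_chains, ether, channel,
                      adduct, always_sum, pl)


#: supported classes.  Sphingolipids (CER, SM) are measured in the
#: hydrolyzed extract; everything else in the total extract.  Positive-mode
#: precursors are [M+H]+ except the neutral classes TAG/DAG/CE which ionize
#: as ammonium adducts.
CLASSES: dict[str, LipidClass] = {
    "CER": _cls("CER", _SPHINGOSINE, "sphingoid-d18:1", 1, CH_CER, "[M+H]+"),
    "SM": _cls("SM", _SM_RESIDUE, "sphingoid-d18:1", 1, CH_HG184_HYD, "[M+H]+"),
    "DAG": _cls("DAG", _GLYCEROL, "glycerol", 2, CH_DAG, "[M+NH4]+",
                always_sum=True),
    "TAG": _cls("TAG", _GLYCEROL, "glycerol", 3, CH_TAG, "[M+NH4]+",
                always_sum=True),
    "CE": _cls("CE", _CHOLESTEROL, "sterol", 1, CH_CE, "[M+NH4]+",
               always_sum=True),
    "PC": _cls("PC", _GPC, "glycerol", 2, CH_HG184, "[M+H]+", pl=True),
    "PC-O": _cls("PC-O", _GPC, "glycerol", 2, CH_HG184, "[M+H]+", ether=True,
                 pl=True),
    "PE": _cls("PE", _GPE, "glycerol", 2, CH_NL141, "[M+H]+", pl=True),
    "PE-O": _cls("PE-O", _GPE, "glycerol", 2, CH_NL141, "[M+H]+", ether=True,
                 pl=True),
    "PS": _cls("PS", _GPS, "glycerol", 2, CH_PS, "[M+H]+", pl=True),
}

PHOSPHOLIPID_CLASSES = ("PC", "PC-O", "PE", "PE-O", "PS")
SPHINGOLIPID_CLASSES = ("CER", "SM")

_CLASS_ALIASES = {
    "CER": "CER", "CER": "CER", "Cer": "CER", "CE": "CE", "SM": "SM",
    "DAG": "DAG", "TAG": "TAG", "PC": "PC", "PE": "PE", "PS": "PS",
    "PC-O": "PC-O", "PC(O)": "PC-O", "PCO": "PC-O",
    "PE-O": "PE-O", "PE(O)": "PE-O", "PEO": "PE-O",
}


# ---------------------------------------------------------------------------
# species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at sum-composition or molecular-species level."""

    lipid_class: LipidClass
    level: str                     # "sum" | "molecular"
    chains: tuple[FattyAcyl, ...]  # sum level: one pseudo-chain of totals

    def __post_init__(self) -> None:
        if self.level not in ("sum", "molecular"):
            raise ValueError(f"bad level {self.level!r}")
        if self.level == "molecular" and len(self.chains) != self.lipid_class.n_chains:
            raise LipidNameError(
                f"{self.lipid_class.name} needs {self.lipid_class.n_chains} "
                f"chains, got {len(self.chains)}")

    @property
    def total_carbons(self) -> int:
        return sum(c.carbons for c in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(c.double_bonds for c in self.chains)

    @property
    def name(self) -> str:
        cls = self.lipid_class.name
        if self.level == "molecular" and self.lipid_class.n_chains > 1:
            return f"{cls} " + "/".join(str(c) for c in self.chains)
        return f"{cls} {self.total_carbons}:{self.total_double_bonds}"

    @property
    def sum_name(self) -> str:
        """Name of the parent sum-composition species."""
        return (f"{self.lipid_class.name} "
                f"{self.total_carbons}:{self.total_double_bonds}")

    @property
    def composition(self) -> ElementalComposition:
        return elemental_composition(self)

    @property
    def neutral_mass(self) -> float:
        return self.composition.monoisotopic_mass

    def mz(self, adduct: str | None = None) -> float:
        """Singly-charged precursor m/z under the class adduct (or override)."""
        shift = ADDUCT_MASS_SHIFT[adduct or self.lipid_class.adduct]
        return self.neutral_mass + shift

    @property
    def negative_mz(self) -> float:
        """[M-H]- precursor m/z used in the fatty-acyl scans."""
        return self.neutral_mass + ADDUCT_MASS_SHIFT["[M-H]-"]

    def __str__(self) -> str:
        return self.name


_CHAIN_RE = re.compile(r"^(?:O-)?(\d+):(\d+)$")


def _parse_chain(token: str, ether: bool = False) -> FattyAcyl:
    m = _CHAIN_RE.match(token)
    if not m:
        raise LipidNameError(f"malformed chain token {token!r}")
    return FattyAcyl(int(m.group(1)), int(m.group(2)),
                     ether=ether or token.startswith("O-"))


def parse_shorthand(name: str) -> LipidSpecies:
    """Parse a shorthand name into a :class:`LipidSpecies`.

    Molecular level iff chains are slash-separated; SM/CER tokens denote the
    N-linked acyl on the implicit d18:1 backbone.  ``O-`` / ``(O)`` class
    tokens map to the ether classes.

    Raises :class:`UnsupportedClassError` for unknown class tokens and
    :class:`LipidNameError` for malformed chain descriptors.
    """
    parts = name.strip().split(None, 1)
    if len(parts) != 2:
        raise LipidNameError(f"cannot split class and chains in {name!r}")
    cls_token, rest = parts
    rest = rest.strip()
    if cls_token in ("PC", "PE") and rest.startswith("O-"):
        cls_token += "-O"
        rest = rest[2:]
    if cls_token not in _CLASS_ALIASES:
        raise UnsupportedClassError(f"unsupported lipid class {cls_token!r}")
    lipid_class = CLASSES[_CLASS_ALIASES[cls_token]]

    chain_tokens = rest.split("/")
    if len(chain_tokens) > 1:
        if len(chain_tokens) != lipid_class.n_chains:
            raise LipidNameError(
                f"{lipid_class.name} takes {lipid_class.n_chains} chains")
        chains = tuple(
            _parse_chain(tok, ether=(lipid_class.ether and i == 0))
            for i, tok in enumerate(chain_tokens))
        return LipidSpecies(lipid_class, "molecular", chains)

    chain = _parse_chain(chain_tokens[0])
    if lipid_class.name in SPHINGOLIPID_CLASSES:
        # single token is the fully-specified N-acyl
        return LipidSpecies(lipid_class, "molecular", (chain,))
    return LipidSpecies(lipid_class, "sum", (chain,))


def format_shorthand(species: LipidSpecies) -> str:
    """Canonical shorthand; inverse of :func:`parse_shorthand`."""
    return species.name


def count_pufa_chains(species: LipidSpecies) -> int:
    """Number of chains with >= 2 double bonds (0, 1 or 2).

    Only meaningful for molecular-level phospholipids; sum-level species
    raise :class:`LevelError` because their chains are not resolved.
    """
    if species.level != "molecular":
        raise LevelError(f"{species.name} is sum-level; chains unresolved")
    return sum(1 for c in species.chains if c.double_bonds >= 2)


def elemental_composition(species: LipidSpecies) -> ElementalComposition:
    """Neutral elemental composition per class formula.

    residue + aggregate chains - one condensation water per chain; ether
    chains replace one ester oxygen by (+2 H, -1 O).  Depends only on the
    sum composition, so sum- and molecular-level species of the same totals
    agree.
    """
    lc = species.lipid_class
    c = species.total_carbons
    d = species.total_double_bonds
    n = lc.n_chains
    if not species.chains:
        return lc.residue
    n_ether = (sum(1 for ch in species.chains if ch.ether)
               if species.level == "molecular" else (1 if lc.ether else 0))
    if lc.ether and n_ether == 0:
        n_ether = 1
    chains_aggregate = ElementalComposition(
        C=c, H=2 * c - 2 * d + 2 * n_ether, O=2 * n - n_ether)
    return lc.residue + chains_aggregate - n * WATER


# ---------------------------------------------------------------------------
# species database
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainSpace:
    """Bounds on the enumerated chain/sum-composition space.

    Even-numbered acyl carbons 12-24 by default; odd chain lengths enter
    only through the ether/odd-chain ambiguity rule.  Sum-level double
    bonds capped at 12 to bound the database.
    """

    acyl_chains: tuple[FattyAcyl, ...] = tuple(
        FattyAcyl(c, d) for c, d in [
            (14, 0), (16, 0), (16, 1), (18, 0), (18, 1), (18, 2), (18, 3),
            (20, 3), (20, 4), (20, 5), (22, 4), (22, 5), (22, 6),
            (24, 0), (24, 1),
        ])
    alkyl_chains: tuple[FattyAcyl, ...] = tuple(
        FattyAcyl(c, d, ether=True) for c, d in [(16, 0), (18, 0), (18, 1)])
    min_chain_carbons: int = 12
    max_chain_carbons: int = 24
    max_sum_double_bonds: int = 12
    n_acyl_carbons: tuple[int, ...] = tuple(range(12, 27, 2))  # SM/CER N-acyl


@dataclass
class SpeciesDatabase:
    """Identification targets: sum species with per-channel m/z, molecular
    pair candidates for the phospholipid classes, and the odd-chain
    interpretations used by the ether/odd assignment rule."""

    species: list[LipidSpecies] = field(default_factory=list)
    molecular_candidates: dict[str, list[LipidSpecies]] = field(
        default_factory=dict)  # sum name -> candidate molecular species
    odd_chain_interpretations: dict[str, LipidSpecies] = field(
        default_factory=dict)  # ether sum name -> odd-chain diacyl reading

    def __post_init__(self) -> None:
        self._by_name = {s.name: s for s in self.species}

    def __len__(self) -> int:
        return len(self.species)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> LipidSpecies:
        return self._by_name[name]

    def species_for_class(self, class_name: str) -> list[LipidSpecies]:
        return [s for s in self.species if s.lipid_class.name == class_name]

    def channel_targets(self, channel: ScanChannel
                        ) -> list[tuple[float, LipidSpecies]]:
        """(target m/z, species) pairs acquired in the given channel.

        Positive quant channels target the class adduct m/z of each sum
        species; fatty-acyl channels target the [M-H]- precursor m/z of
        every sum species with a candidate pair containing that chain.
        """
        if channel.scan_type.startswith("fa-"):
            c, d = map(int, channel.scan_type[3:].split("_"))
            chain = FattyAcyl(c, d)
            out = []
            for sum_name, candidates in self.molecular_candidates.items():
                if any(chain in (FattyAcyl(x.carbons, x.double_bonds)
                                 for x in mol.chains if not x.ether)
                       for mol in candidates):
                    s = self._by_name[sum_name]
                    out.append((s.negative_mz, s))
            return sorted(out, key=lambda t: t[0])
        out = [(s.mz(), s) for s in self.species
               if s.lipid_class.quant_channel == channel]
        return sorted(out, key=lambda t: t[0])

    def fa_channels(self) -> list[ScanChannel]:
        chains = set()
        for candidates in self.molecular_candidates.values():
            for mol in candidates:
                for ch in mol.chains:
                    if not ch.ether:
                        chains.add((ch.carbons, ch.double_bonds))
        return [fa_channel(c, d) for c, d in sorted(chains)]

    # -- CSV round trip -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.species:
            rows.append({
                "name": s.name,
                "class": s.lipid_class.name,
                "level": s.level,
                "chains": "/".join(str(c) for c in s.chains),
                "formula": s.composition.hill_formula,
                "mz_quant": round(s.mz(), 4),
                "mz_negative": round(s.negative_mz, 4),
                "quant_channel": s.lipid_class.quant_channel.id,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpeciesDatabase":
        frame = pd.read_csv(path)
        species = [parse_shorthand(n) for n in frame["name"]]
        return cls(species=species)


def _enumerate_sum_species(lipid_class: LipidClass, space: ChainSpace
                           ) -> list[LipidSpecies]:
    n = lipid_class.n_chains
    if lipid_class.name in SPHINGOLIPID_CLASSES:
        return [LipidSpecies(lipid_class, "molecular", (FattyAcyl(c, d),))
                for c in space.n_acyl_carbons
                for d in (0, 1)]
    out = []
    for total_c in range(n * space.min_chain_carbons,
                         n * space.max_chain_carbons + 1, 2):
        max_d = min(space.max_sum_double_bonds, total_c // 2)
        for total_d in range(0, max_d + 1):
            out.append(LipidSpecies(lipid_class, "sum",
                                    (FattyAcyl(total_c, total_d),)))
    return out


def _enumerate_molecular(lipid_class: LipidClass, space: ChainSpace
                         ) -> dict[str, list[LipidSpecies]]:
    """Candidate chain pairs per sum composition for one PL class."""
    out: dict[str, list[LipidSpecies]] = {}
    if lipid_class.ether:
        pairs = itertools.product(space.alkyl_chains, space.acyl_chains)
    else:
        pairs = itertools.combinations_with_replacement(space.acyl_chains, 2)
    for a, b in pairs:
        mol = LipidSpecies(lipid_class, "molecular", (a, b))
        out.setdefault(mol.sum_name, []).append(mol)
    return out


def build_species_database(classes: dict[str, LipidClass] | None = None,
                           chain_space: ChainSpace | None = None,
                           ) -> SpeciesDatabase:
    """Enumerate the identification database over the configured chain space.

    Every species carries a precursor m/z per relevant scan channel; the
    database is sorted by class then m/z and contains no duplicate names.
    Odd-chain diacyl interpretations of ether species are recorded for the
    ether-preference assignment rule but are not identification targets.
    """
    classes = classes if classes is not None else CLASSES
    space = chain_space or ChainSpace()
    species: list[LipidSpecies] = []
    molecular: dict[str, list[LipidSpecies]] = {}
    odd: dict[str, LipidSpecies] = {}

    for lc in classes.values():
        entries = _enumerate_sum_species(lc, space)
        entries.sort(key=lambda s: s.mz())
        species.extend(entries)
        if lc.is_phospholipid:
            cand = _enumerate_molecular(lc, space)
            for sum_name, mols in cand.items():
                if sum_name in {s.name for s in entries}:
                    molecular.setdefault(sum_name, []).extend(mols)
        if lc.ether:
            diacyl_cls = classes.get(lc.name.split("-")[0])
            if diacyl_cls is not None:
                for s in entries:
                    c, d = s.total_carbons, s.total_double_bonds
                    if c - 1 >= 2 and d <= (c - 1) // 2:
                        odd[s.name] = LipidSpecies(
                            diacyl_cls, "sum", (FattyAcyl(c - 1, d),))

    seen: set[str] = set()
    unique = []
    for s in species:
        if s.name not in seen:
            seen.add(s.name)
            unique.append(s)
    return SpeciesDatabase(species=unique, molecular_candidates=molecular,
                           odd_chain_interpretations=odd)
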