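"""Synthetic strain-set generator with planted ground truth.

The generator emulates the data a comparative BGC study consumes: a set of
closely related bacterial strains structured into clades, each carrying

* ~30 conserved single-copy housekeeping genes evolving by Jukes-Cantor
  substitution along a known phylogeny (plus the standalone ``sfp`` gene),
* per-strain biosynthetic gene cluster (BGC) regions — ordered genes with
  NRPS/PKS-style domain annotations — whose sequences evolve under the same
  substitution process,
* clade-conserved whole-gene deletions and fixed-position frameshift
  indels, inherited by every descendant of the clade ancestor,
* rare horizontal transfer of a whole BGC into a clade it is absent from.

Strains are written as GenBank files plus a ``truth.json`` ground-truth
table (true tree, region-to-family map, realized events, MLSA gene names).
Everything is driven by a single integer seed; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._tree import Node
from .genome_model import (
    BGCRegion,
    Contig,
    DomainAnnotation,
    Gene,
    GenomeRecord,
    write_genbank,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = sorted(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
)

OUTGROUP_ACCESSION = "SYNOUT"

#: canonical 30 housekeeping gene names used for the MLSA stage
HOUSEKEEPING_NAMES = [
    "argS", "aspS", "dnaJ", "dnaN", "ffh", "ftsZ", "fusA", "glnA", "groL",
    "gyrA", "gyrB", "hisS", "ileS", "infB", "leuS", "ligA", "murC", "pheT",
    "polA", "pyrG", "recA", "rplB", "rpoB", "rpsB", "rpsC", "secA", "serS",
    "thrS", "tufA", "valS",
]

# BGC family blueprints: (family, product class, genes).  Each gene is
# (name, nt length, domains) with amino-acid half-open domain intervals;
# AMP-binding domains carry a predicted substrate.  The iturinic family's
# seven adenylation specificities spell the mycosubtilin signature.
_D = DomainAnnotation
FAMILY_BLUEPRINTS: list[tuple[str, str, list[tuple[str, int, list[DomainAnnotation]]]]] = [
    (
        "plipastatin",
        "NRPS",
        # two-module megasynthetase genes (C-A-PP x2), terminal gene with TE;
        # dense domain content so losing one gene does not eject a region
        # from its family, matching real NRPS loci
        [
            ("ppsA", 5400, [_D("Condensation", 10, 300), _D("AMP-binding", 330, 780, "glu"), _D("PP-binding", 810, 880), _D("Condensation", 910, 1200), _D("AMP-binding", 1230, 1680, "orn"), _D("PP-binding", 1710, 1780)]),
            ("ppsB", 5400, [_D("Condensation", 10, 300), _D("AMP-binding", 330, 780, "tyr"), _D("PP-binding", 810, 880), _D("Condensation", 910, 1200), _D("AMP-binding", 1230, 1680, "thr"), _D("PP-binding", 1710, 1780)]),
            ("ppsC", 5400, [_D("Condensation", 10, 300), _D("AMP-binding", 330, 780, "glu"), _D("PP-binding", 810, 880), _D("Condensation", 910, 1200), _D("AMP-binding", 1230, 1680, "ala"), _D("PP-binding", 1710, 1780)]),
            ("ppsD", 5400, [_D("Condensation", 10, 300), _D("AMP-binding", 330, 780, "pro"), _D("PP-binding", 810, 880), _D("Condensation", 910, 1200), _D("AMP-binding", 1230, 1680, "gln"), _D("PP-binding", 1710, 1780)]),
            ("ppsE", 3300, [_D("Condensation", 10, 300), _D("AMP-binding", 330, 780, "ile"), _D("PP-binding", 810, 880), _D("TE", 950, 1080)]),
        ],
    ),
    (
        "fengycin",
        "NRPS",
        [
            ("fenA", 5400, [_D("Condensation", 10, 300), _D("AMP-binding", 330, 780, "glu"), _D("PP-binding", 810, 880), _D("Condensation", 910, 1200), _D("AMP-binding", 1230, 1680, "orn"), _D("PP-binding", 1710, 1780)]),
            ("fenB", 5400, [_D("Condensation", 10, 300), _D("AMP-binding", 330, 780, "tyr"), _D("PP-binding", 810, 880), _D("Condensation", 910, 1200), _D("AMP-binding", 1230, 1680, "thr"), _D("PP-binding", 1710, 1780)]),
            ("fenC", 5400, [_D("Condensation", 10, 300), _D("AMP-binding", 330, 780, "glu"), _D("PP-binding", 810, 880), _D("Condensation", 910, 1200), _D("AMP-binding", 1230, 1680, "val"), _D("PP-binding", 1710, 1780)]),
            ("fenD", 5820, [_D("Condensation", 10, 300), _D("AMP-binding", 330, 780, "ala"), _D("PP-binding", 810, 880), _D("Condensation", 910, 1200), _D("AMP-binding", 1230, 1680, "pro"), _D("PP-binding", 1710, 1780), _D("TE", 1800, 1930)]),
            ("fenE", 1800, [_D("AMP-binding", 30, 480, "ile"), _D("PP-binding", 510, 580)]),
        ],
    ),
    (
        "surfactin",
        "NRPS",
        [
            ("srfAA", 3300, [_D("Condensation", 10, 300), _D("AMP-binding", 330, 780, "glu"), _D("PP-binding", 810, 880)]),
            ("srfAB", 3300, [_D("Condensation", 10, 300), _D("AMP-binding", 330, 780, "leu"), _D("PP-binding", 810, 880)]),
            ("srfAC", 2400, [_D("Condensation", 10, 300), _D("AMP-binding", 330, 700, "leu"), _D("TE", 720, 790)]),
            ("srfAD", 720, [_D("TE", 20, 220)]),
        ],
    ),
    (
        "iturin",
        "NRPS/PKS hybrid",
        [
            ("ituD", 1200, [_D("AT", 20, 350)]),
            ("ituA", 3300, [_D("KS", 10, 420), _D("AMP-binding", 450, 900, "asn"), _D("PP-binding", 950, 1020)]),
            ("ituB", 3600, [_D("AMP-binding", 10, 340, "tyr"), _D("PP-binding", 350, 420), _D("AMP-binding", 430, 760, "asn"), _D("PP-binding", 770, 840), _D("AMP-binding", 850, 1180, "gln")]),
            ("ituC", 3600, [_D("AMP-binding", 10, 340, "pro"), _D("PP-binding", 350, 420), _D("AMP-binding", 430, 760, "ser"), _D("PP-binding", 770, 840), _D("AMP-binding", 850, 1180, "asn")]),
        ],
    ),
    (
        "bacillaene",
        "NRPS/PKS hybrid",
        [
            ("baeJ", 3000, [_D("KS", 10, 420), _D("AT", 450, 770), _D("PP-binding", 800, 870)]),
            ("baeL", 2700, [_D("KS", 10, 420), _D("AT", 450, 770)]),
            ("baeN", 2400, [_D("Condensation", 10, 300), _D("AMP-binding", 330, 700, "gly"), _D("PP-binding", 720, 790)]),
        ],
    ),
    (
        "sesquarterpene",
        "terpene",
        [
            ("ytpB", 900, [_D("Terpene_synth_C", 10, 280)]),
            ("sqtA", 600, [_D("Terpene_cyclase", 10, 180)]),
        ],
    ),
]

SFP_LENGTH = 675


class SimulationConfigError(ValueError):
    """Raised before any file is written when a config is inconsistent."""


@dataclass(frozen=True)
class PlantedEvent:
    """A clade-conserved event applied on the named clade's ancestral branch.

    ``kind`` is one of ``gene_deletion``, ``frameshift_indel``,
    ``family_loss``, ``hgt_gain``.  For frameshifts, ``position`` is the
    1-based nucleotide position on the reference (root) gene and
    ``indel_length`` the number of deleted bases (must not be a multiple of
    3).  An empty ``family`` targets a standalone gene (e.g. ``sfp``) by
    name.  For ``hgt_gain``, ``clade`` names the *recipient* clade.
    """

    kind: str
    clade: str
    family: str = ""
    gene: str = ""
    position: int | None = None
    indel_length: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gene_deletion", "frameshift_indel", "family_loss", "hgt_gain"):
            raise SimulationConfigError(f"unknown event kind {self.kind!r}")
        if self.kind == "frameshift_indel":
            if self.indel_length is None or self.indel_length % 3 == 0:
                raise SimulationConfigError("frameshift indel_length must not be a multiple of 3")
            if self.position is None or self.position < 1:
                raise SimulationConfigError("frameshift position must be a 1-based position")


@dataclass
class SimConfig:
    n_strains: int = 16
    n_clades: int = 4
    n_housekeeping: int = 30
    n_bgc_families: int = 6
    substitution_rate: float = 0.04  # expected substitutions/site, root to tip
    planted_events: list[PlantedEvent] = field(default_factory=list)
    hgt_probability: float = 0.0
    seed: int = 42
    include_outgroup: bool = True
    #: restrict a family to the named clades; families not listed are global
    family_clades: dict[str, list[str]] = field(default_factory=dict)
    #: keep planted indel sites out of homopolymer context so leftmost
    #: placement recovers the planted coordinate exactly
    avoid_homopolymer: bool = True

    def __post_init__(self) -> None:
        if self.n_strains < 3:
            raise SimulationConfigError("need at least 3 strains")
        if self.n_clades < 1 or self.n_strains < 2 * self.n_clades:
            raise SimulationConfigError("need at least 2 strains per clade")
        if not 0 <= self.hgt_probability <= 1:
            raise SimulationConfigError("hgt_probability must be in [0,1]")
        if self.substitution_rate < 0:
            raise SimulationConfigError("substitution_rate must be >= 0")
        if self.n_bgc_families < 0:
            raise SimulationConfigError("n_bgc_families must be >= 0")


@dataclass
class TruthTable:
    """Machine-readable ground truth accompanying a simulated dataset."""

    true_tree: str
    family_membership: dict[str, str]
    event_realizations: dict[str, list[dict]]
    mlsa_gene_names: list[str]
    clade_leaves: dict[str, list[str]]
    outgroup: str | None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        return cls(**json.loads(Path(path).read_text()))


def default_config(seed: int = 42) -> SimConfig:
    """The default study conditions: 16 strains in 4 clades, 6 BGC families,
    2 clade-conserved gene deletions, 2 clade-conserved frameshifts
    (single-base at position 232 of ppsE; 2-base at 3126 of fenD) and one
    horizontal family transfer."""
    return SimConfig(
        n_strains=16,
        n_clades=4,
        n_housekeeping=30,
        n_bgc_families=6,
        substitution_rate=0.04,
        seed=seed,
        planted_events=[
            PlantedEvent("gene_deletion", clade="C2", family="plipastatin", gene="ppsD"),
            PlantedEvent("gene_deletion", clade="C4", family="fengycin", gene="fenE"),
            PlantedEvent("frameshift_indel", clade="C3", family="plipastatin", gene="ppsE",
                         position=232, indel_length=1),
            PlantedEvent("frameshift_indel", clade="C2", family="fengycin", gene="fenD",
                         position=3126, indel_length=2),
            PlantedEvent("hgt_gain", clade="C4", family="iturin"),
        ],
        family_clades={"iturin": ["C1", "C2", "C3"]},
    )


# ---------------------------------------------------------------------------
# sequence machinery


def random_coding_sequence(length_nt: int, rng: np.random.Generator) -> np.ndarray:
    """Random stop-free coding sequence (ATG ... TAA) as a uint8 base array."""
    assert length_nt % 3 == 0 and length_nt >= 9
    n_mid = length_nt // 3 - 2
    codons = ["ATG"] + [_NON_STOP_CODONS[i] for i in rng.integers(0, len(_NON_STOP_CODONS), n_mid)] + ["TAA"]
    return np.frombuffer("".join(codons).encode(), dtype=np.uint8).copy()


def evolve_sequence(
    seq: np.ndarray,
    branch_length: float,
    rng: np.random.Generator,
    protected: frozenset[int] = frozenset(),
) -> np.ndarray:
    """One branch of Jukes-Cantor evolution: Poisson(branch_length * L)
    substitution events at uniform positions, each to a uniform other base."""
    out = seq.copy()
    if branch_length <= 0:
        return out
    n_events = rng.poisson(branch_length * len(seq))
    if n_events == 0:
        return out
    positions = rng.integers(0, len(seq), n_events)
    shifts = rng.integers(1, 4, n_events)
    for pos, shift in zip(positions, shifts):
        if int(pos) in protected:
            continue
        idx = int(np.searchsorted(_BASES, out[pos]))
        out[pos] = _BASES[(idx + shift) % 4]
    return out


def _seq_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode()


def mutate_to_identity(sequence: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute exactly round((1-identity)*len) positions (no indels)."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    n_mut = int(round((1.0 - identity) * len(arr)))
    positions = rng.choice(len(arr), size=n_mut, replace=False)
    for pos in positions:
        idx = int(np.searchsorted(_BASES, arr[pos]))
        arr[pos] = _BASES[(idx + int(rng.integers(1, 4))) % 4]
    return _seq_str(arr)


# ---------------------------------------------------------------------------
# tree construction


def _random_topology(leaf_names: list[str], rng: np.random.Generator) -> Node:
    """Uniform random labeled bifurcating topology via sequential addition:
    leaf k+1 attaches to one of the 2k-3 edges uniformly."""
    if len(leaf_names) == 1:
        return Node(leaf_names[0])
    root = Node(children=[Node(leaf_names[0]), Node(leaf_names[1])])
    for name in leaf_names[2:]:
        edges = [n for n in root.walk() if n is not root]
        target = edges[int(rng.integers(0, len(edges)))]
        parent = next(p for p in root.walk() if target in p.children)
        joint = Node(children=[target, Node(name)])
        parent.children[parent.children.index(target)] = joint
    return root


def build_true_tree(config: SimConfig, rng: np.random.Generator) -> tuple[Node, dict[str, list[str]]]:
    """Clade-structured random tree with exponential branch lengths scaled so
    the mean ingroup root-to-tip path equals ``substitution_rate``.
    Inter-clade (backbone) branches are drawn 3x longer before scaling and
    every branch is floored at substitution_rate/10, giving clades strong,
    bootstrap-recoverable separation."""
    accessions = [f"SYN{i:03d}" for i in range(1, config.n_strains + 1)]
    sizes = [len(chunk) for chunk in np.array_split(np.arange(config.n_strains), config.n_clades)]
    clade_leaves: dict[str, list[str]] = {}
    clade_roots: list[Node] = []
    pos = 0
    for i, size in enumerate(sizes, start=1):
        names = accessions[pos : pos + size]
        pos += size
        sub = _random_topology(names, rng)
        sub.name = f"C{i}"
        clade_leaves[f"C{i}"] = names
        clade_roots.append(sub)

    if len(clade_roots) == 1:
        ingroup = clade_roots[0]
    else:
        # backbone joining the clade roots
        placeholder_names = [r.name for r in clade_roots]
        ingroup = _random_topology(placeholder_names, rng)
        by_name = {r.name: r for r in clade_roots}
        for node in list(ingroup.walk()):
            for k, child in enumerate(node.children):
                if child.is_leaf and child.name in by_name:
                    node.children[k] = by_name[child.name]

    clade_names = set(clade_leaves)
    for node in ingroup.walk():
        if node.is_leaf:
            node.length = float(rng.exponential(1.0))
        else:
            node.length = float(rng.exponential(3.0))  # backbone / clade stems
    ingroup.length = 0.0

    if config.substitution_rate > 0:
        depths = []

        def _depth(node: Node, acc: float) -> None:
            acc += node.length
            if node.is_leaf:
                depths.append(acc)
            for c in node.children:
                _depth(c, acc)

        _depth(ingroup, -ingroup.length)
        scale = config.substitution_rate / float(np.mean(depths))
        floor = config.substitution_rate / 10.0
        for node in ingroup.walk():
            if node is not ingroup:
                node.length = max(node.length * scale, floor)
    else:
        for node in ingroup.walk():
            node.length = 0.0

    if config.include_outgroup:
        out = Node(OUTGROUP_ACCESSION, length=1.5 * config.substitution_rate)
        ingroup.length = 0.25 * config.substitution_rate
        root = Node("ROOT", children=[ingroup, out])
    else:
        root = ingroup
    return root, clade_leaves


# ---------------------------------------------------------------------------
# the simulator proper


class _GeneState:
    __slots__ = ("seq", "protected", "fs_aa_prefix")

    def __init__(self, seq: np.ndarray, protected: frozenset[int] = frozenset(),
                 fs_aa_prefix: int | None = None):
        self.seq = seq
        self.protected = protected
        self.fs_aa_prefix = fs_aa_prefix  # aa prefix still in frame, if frameshifted

    def copy(self) -> "_GeneState":
        return _GeneState(self.seq, self.protected, self.fs_aa_prefix)


def _family_table(config: SimConfig) -> list[tuple[str, str, list[tuple[str, int, list[DomainAnnotation]]]]]:
    table = list(FAMILY_BLUEPRINTS[: config.n_bgc_families])
    for i in range(len(table), config.n_bgc_families):
        genes = [(f"nrp{i}{chr(ord('A') + j)}", 1500,
                  [_D("Condensation", 10, 250), _D("AMP-binding", 270, 480, "ala")])
                 for j in range(3)]
        table.append((f"family{i + 1}", "NRPS", genes))
    return table


def _housekeeping_names(config: SimConfig) -> list[str]:
    names = list(HOUSEKEEPING_NAMES[: config.n_housekeeping])
    for i in range(len(names), config.n_housekeeping):
        names.append(f"hkg{i + 1:02d}")
    return names


def _validate_events(config: SimConfig, clade_leaves: dict[str, list[str]],
                     families: dict[str, dict], hk: dict[str, np.ndarray]) -> None:
    for ev in config.planted_events:
        if ev.clade not in clade_leaves:
            raise SimulationConfigError(f"event references unknown clade {ev.clade!r}")
        if ev.kind == "hgt_gain":
            if ev.family not in families:
                raise SimulationConfigError(f"event references unknown family {ev.family!r}")
            continue
        if ev.family:
            if ev.family not in families:
                raise SimulationConfigError(f"event references unknown family {ev.family!r}")
            if ev.kind != "family_loss" and ev.gene not in families[ev.family]["genes"]:
                raise SimulationConfigError(
                    f"event references unknown gene {ev.gene!r} of family {ev.family!r}")
        else:
            if ev.gene not in hk:
                raise SimulationConfigError(f"event references unknown standalone gene {ev.gene!r}")
        if ev.kind == "frameshift_indel":
            ref_len = (len(families[ev.family]["genes"][ev.gene]) if ev.family
                       else len(hk[ev.gene]))
            if ev.position + abs(ev.indel_length) - 1 > ref_len:
                raise SimulationConfigError(
                    f"frameshift at {ev.position} exceeds {ev.gene} length {ref_len}")


def _fix_homopolymer_context(seq: np.ndarray, position: int, length: int,
                             rng: np.random.Generator) -> None:
    """Ensure leftmost placement of a deletion at 1-based ``position`` is
    unique: the base before the run must differ from the run's last base."""
    s = position - 1
    if s == 0:
        return
    while seq[s - 1] == seq[s + length - 1]:
        idx = int(np.searchsorted(_BASES, seq[s + length - 1]))
        seq[s + length - 1] = _BASES[(idx + 1 + int(rng.integers(0, 3))) % 4]


def _apply_frameshift(state: _GeneState, ev: PlantedEvent) -> None:
    length = ev.indel_length
    s = ev.position - 1
    state.seq = np.concatenate([state.seq[:s], state.seq[s + length:]])
    state.protected = frozenset(
        p if p < s else p - length for p in state.protected if not s <= p < s + length
    )
    prefix = s // 3
    state.fs_aa_prefix = prefix if state.fs_aa_prefix is None else min(state.fs_aa_prefix, prefix)


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> TruthTable:
    """Run the simulation; write one GenBank file per strain plus truth.json.

    Returns the :class:`TruthTable` (also serialized as ``truth.json``).
    Deterministic: identical config (including seed) gives byte-identical
    output files.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)

    root, clade_leaves = build_true_tree(config, rng)

    hk_names = _housekeeping_names(config)
    hk_root: dict[str, np.ndarray] = {}
    for name in hk_names:
        length = 450 + 3 * int(rng.integers(0, 151))  # 450..900 nt
        hk_root[name] = random_coding_sequence(length, rng)
    hk_root["sfp"] = random_coding_sequence(SFP_LENGTH, rng)

    families: dict[str, dict] = {}
    for fam_name, pclass, gene_specs in _family_table(config):
        genes = {g: random_coding_sequence(length, rng) for g, length, _doms in gene_specs}
        families[fam_name] = {
            "product_class": pclass,
            "genes": genes,
            "order": [g for g, _l, _d in gene_specs],
            "domains": {g: doms for g, _l, doms in gene_specs},
            "clades": config.family_clades.get(fam_name),  # None => all clades
        }

    _validate_events(config, clade_leaves, families, hk_root)

    # pin down frameshift contexts and protect substitution windows
    protected: dict[tuple[str, str], set[int]] = {}
    for ev in config.planted_events:
        if ev.kind != "frameshift_indel":
            continue
        seq = families[ev.family]["genes"][ev.gene] if ev.family else hk_root[ev.gene]
        if config.avoid_homopolymer:
            _fix_homopolymer_context(seq, ev.position, ev.indel_length, rng)
        window = range(max(0, ev.position - 5), min(len(seq), ev.position + ev.indel_length + 4))
        protected.setdefault((ev.family, ev.gene), set()).update(window)

    events_by_clade: dict[str, list[PlantedEvent]] = {}
    for ev in config.planted_events:
        if ev.kind != "hgt_gain":
            events_by_clade.setdefault(ev.clade, []).append(ev)

    # initial state at the root of the whole tree
    state0: dict[tuple[str, str], _GeneState] = {}
    for name, seq in hk_root.items():
        state0[("", name)] = _GeneState(seq, frozenset(protected.get(("", name), ())))
    for fam_name, fam in families.items():
        for g, seq in fam["genes"].items():
            state0[(fam_name, g)] = _GeneState(seq, frozenset(protected.get((fam_name, g), ())))

    leaf_states: dict[str, dict[tuple[str, str], _GeneState]] = {}

    def _recurse(node: Node, state: dict) -> None:
        state = {k: v.copy() for k, v in state.items()}
        for key in sorted(state):
            st = state[key]
            st.seq = evolve_sequence(st.seq, node.length, rng, st.protected)
        for ev in events_by_clade.get(node.name, []):
            if ev.kind == "gene_deletion":
                state.pop((ev.family, ev.gene), None)
            elif ev.kind == "frameshift_indel":
                key = (ev.family, ev.gene)
                if key in state:
                    _apply_frameshift(state[key], ev)
        if node.is_leaf:
            leaf_states[node.name] = state
        for child in node.children:
            _recurse(child, state)

    _recurse(root, state0)

    # family presence per leaf: clade-determined, minus clade-conserved losses
    present_by_clade: dict[str, set[str]] = {
        cname: {f for f, fam in families.items()
                if fam["clades"] is None or cname in fam["clades"]}
        for cname in clade_leaves
    }
    leaf_clade = {leaf: c for c, ls in clade_leaves.items() for leaf in ls}
    leaf_present: dict[str, set[str]] = {}
    event_realizations: dict[str, list[dict]] = {}
    for leaf in leaf_states:
        if leaf == OUTGROUP_ACCESSION:
            leaf_present[leaf] = set()
            event_realizations[leaf] = []
            continue
        clade = leaf_clade[leaf]
        lost = {ev.family for ev in events_by_clade.get(clade, ())
                if ev.kind == "family_loss"}
        leaf_present[leaf] = present_by_clade[clade] - lost
        event_realizations[leaf] = [asdict(ev) for ev in events_by_clade.get(clade, ())]

    # horizontal transfers
    hgt_realized: list[tuple[str, str]] = []  # (leaf, family)
    for ev in config.planted_events:
        if ev.kind != "hgt_gain":
            continue
        candidates = [l for l in sorted(clade_leaves[ev.clade]) if ev.family not in leaf_present[l]]
        if not candidates:
            raise SimulationConfigError(
                f"hgt_gain: family {ev.family!r} already present throughout clade {ev.clade!r}")
        recipient = candidates[int(rng.integers(0, len(candidates)))]
        hgt_realized.append((recipient, ev.family))
    if config.hgt_probability > 0:
        for fam_name in sorted(families):
            for leaf in sorted(l for l in leaf_states if l != OUTGROUP_ACCESSION):
                if fam_name not in leaf_present[leaf] and rng.random() < config.hgt_probability:
                    hgt_realized.append((leaf, fam_name))
    for leaf, fam_name in hgt_realized:
        leaf_present[leaf] = leaf_present[leaf] | {fam_name}
        for g, seq in families[fam_name]["genes"].items():
            leaf_states[leaf][(fam_name, g)] = _GeneState(seq.copy())
        event_realizations.setdefault(leaf, []).append(
            {"kind": "hgt_gain", "clade": "", "family": fam_name, "gene": "",
             "position": None, "indel_length": None})

    # ---- emit GenBank files + truth ----
    family_membership: dict[str, str] = {}
    records: list[GenomeRecord] = []
    mlsa_names = [n for n in hk_names]

    for leaf in sorted(leaf_states):
        state = leaf_states[leaf]
        is_outgroup = leaf == OUTGROUP_ACCESSION
        genes: list[Gene] = []
        regions: list[BGCRegion] = []
        pos = 100
        locus_idx = 0

        def _add_gene(name: str, seq: np.ndarray, strand: int, product: str,
                      domains: list[DomainAnnotation], fs_prefix: int | None) -> Gene:
            nonlocal pos, locus_idx
            locus_idx += 1
            aa_len = len(seq) // 3
            kept = []
            for d in domains:
                limit = aa_len if fs_prefix is None else min(aa_len, fs_prefix)
                if d.aa_end <= limit:
                    kept.append(d)
            g = Gene(
                locus_tag=f"{leaf}_{locus_idx:05d}",
                name=name,
                start=pos,
                end=pos + len(seq),
                strand=strand,
                sequence=_seq_str(seq),
                product=product,
                domains=kept,
            )
            pos += len(seq) + 50
            genes.append(g)
            return g

        standalone = hk_names + ([] if is_outgroup else ["sfp"])
        for i, name in enumerate(standalone):
            st = state[("", name)]
            _add_gene(name, st.seq, 1 if i % 2 == 0 else -1,
                      "hypothetical housekeeping protein" if name != "sfp"
                      else "4'-phosphopantetheinyl transferase", [], st.fs_aa_prefix)

        region_idx = 0
        for fam_name in sorted(leaf_present[leaf]):
            fam = families[fam_name]
            region_idx += 1
            rstart = pos - 25
            fam_genes = []
            for gname in fam["order"]:
                key = (fam_name, gname)
                if key not in state:
                    continue  # clade-conserved gene deletion
                st = state[key]
                fam_genes.append(
                    _add_gene(gname, st.seq, 1, f"{fam_name} biosynthesis protein",
                              fam["domains"][gname], st.fs_aa_prefix))
            rend = pos - 25
            rid = f"{leaf}_r{region_idx}"
            regions.append(BGCRegion(
                region_id=rid, genome_accession=leaf, contig_id=leaf,
                start=rstart, end=rend, product_class=fam["product_class"],
                genes=fam_genes))
            family_membership[rid] = fam_name

        contig = Contig(id=leaf, length=pos + 100, genes=genes)
        strain = "OUT-1" if is_outgroup else f"P{int(leaf[3:])}"
        organism = "Bacillus megaterium" if is_outgroup else "Bacillus synthensis"
        records.append(GenomeRecord(
            accession=leaf, organism=organism, strain=strain,
            contigs=[contig], regions=regions))

    truth = TruthTable(
        true_tree=root.to_newick(lengths=True),
        family_membership=family_membership,
        event_realizations={k: sorted(v, key=lambda d: (d["kind"], d["family"], d["gene"]))
                            for k, v in sorted(event_realizations.items())},
        mlsa_gene_names=mlsa_names,
        clade_leaves={k: sorted(v) for k, v in clade_leaves.items()},
        outgroup=OUTGROUP_ACCESSION if config.include_outgroup else None,
    )

    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_genbank(rec, out_dir / f"{rec.accession}.gbk")
    truth.to_json(out_dir / "truth.json")
    logger.info("simulated %d strains into %s", len(records), out_dir)
    return truth


def family_reference_sequences(config: SimConfig) -> dict[str, dict[str, str]]:
    """Root (ancestral) gene sequences per family, regenerated from the seed.

    Replays the generator's deterministic draw order up to family creation,
    so the returned sequences equal the references the dataset evolved from.
    """
    rng = np.random.default_rng(config.seed)
    build_true_tree(config, rng)
    hk_names = _housekeeping_names(config)
    hk_root = {}
    for name in hk_names:
        length = 450 + 3 * int(rng.integers(0, 151))
        hk_root[name] = random_coding_sequence(length, rng)
    hk_root["sfp"] = random_coding_sequence(SFP_LENGTH, rng)
    families = {}
    for fam_name, _pclass, gene_specs in _family_table(config):
        families[fam_name] = {
            g: random_coding_sequence(length, rng) for g, length, _doms in gene_specs
        }
    # replay homopolymer-context fixes so references match planted coordinates
    for ev in config.planted_events:
        if ev.kind != "frameshift_indel":
            continue
        seq = families[ev.family][ev.gene] if ev.family else hk_root[ev.gene]
        if config.avoid_homopolymer:
            _fix_homopolymer_context(seq, ev.position, ev.indel_length, rng)
    out = {fam: {g: _seq_str(s) for g, s in genes.items()} for fam, genes in families.items()}
    out["_standalone"] = {g: _seq_str(s) for g, s in hk_root.items()}
    return out


def export_reference_bundles(
    config: SimConfig,
    out_dir: str | Path,
    families: tuple[str, ...] = ("plipastatin", "fengycin"),
) -> dict:
    """Write family-reference bundles (JSON + FASTA + domain TSV) and the
    sfp reference FASTA for a simulated dataset, in the format the pipeline
    consumes.  Returns {"family_files": [...], "sfp_fasta": ...}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refs = family_reference_sequences(config)
    blueprints = {f[0]: f for f in _family_table(config)}
    family_files = []
    for fam in families:
        _name, _pclass, gene_specs = blueprints[fam]
        fasta = out_dir / f"{fam}.fasta"
        fasta.write_text("".join(f">{g}\n{refs[fam][g]}\n" for g, _l, _d in gene_specs))
        dom_tsv = out_dir / f"{fam}_domains.tsv"
        with open(dom_tsv, "w") as fh:
            fh.write("gene\tdomain_type\taa_start\taa_end\tspecificity\n")
            for g, _l, doms in gene_specs:
                for d in doms:
                    fh.write(f"{g}\t{d.domain_type}\t{d.aa_start}\t{d.aa_end}\t{d.specificity}\n")
        bundle = out_dir / f"{fam}.json"
        bundle.write_text(json.dumps({
            "family_name": fam,
            "core_genes": [g for g, _l, _d in gene_specs],
            "fasta": fasta.name,
            "domains_tsv": dom_tsv.name,
        }, indent=1) + "\n")
        family_files.append(str(bundle))
    sfp_fasta = out_dir / "sfp.fasta"
    sfp_fasta.write_text(f">sfp\n{refs['_standalone']['sfp']}\n")
    return {"family_files": family_files, "sfp_fasta": str(sfp_fasta)}


# ---------------------------------------------------------------------------
# merged-region fixture for the split stage


def simulate_merged_region(
    seed: int = 0, boundary_identity: float = 1.0
) -> tuple[BGCRegion, dict[str, list[str]]]:
    """A merged two-cluster region with dacC/yngH boundary genes between the
    halves, plus reference panels for both boundary genes.

    ``boundary_identity`` mutates the region's boundary-gene copies away
    from the panel references (e.g. 0.85 to fall below a 90% threshold).
    Returns ``(region, panels)`` with ``panels = {"dacC": [...], "yngH": [...]}``.
    """
    rng = np.random.default_rng(seed)
    dacC_ref = _seq_str(random_coding_sequence(1164, rng))
    yngH_ref = _seq_str(random_coding_sequence(1350, rng))
    panels = {
        "dacC": [dacC_ref, mutate_to_identity(dacC_ref, 0.95, rng)],
        "yngH": [yngH_ref, mutate_to_identity(yngH_ref, 0.95, rng)],
    }

    layout: list[tuple[str, str, list[DomainAnnotation]]] = []
    for name, length, doms in FAMILY_BLUEPRINTS[1][2]:  # fengycin genes
        layout.append((name, _seq_str(random_coding_sequence(length, rng)), doms))
    dacC_copy = dacC_ref if boundary_identity >= 1.0 else mutate_to_identity(
        dacC_ref, boundary_identity, rng)
    yngH_copy = yngH_ref if boundary_identity >= 1.0 else mutate_to_identity(
        yngH_ref, boundary_identity, rng)
    layout.append(("dacC", dacC_copy, [_D("Peptidase_S11", 10, 360)]))
    layout.append(("yngH", yngH_copy, [_D("Biotin_carb", 10, 420)]))
    for name, length, doms in FAMILY_BLUEPRINTS[3][2]:  # iturin genes
        layout.append((name, _seq_str(random_coding_sequence(length, rng)), doms))

    genes = []
    pos = 100
    for i, (name, seq, doms) in enumerate(layout, start=1):
        genes.append(Gene(
            locus_tag=f"MRG_{i:05d}", name=name, start=pos, end=pos + len(seq),
            strand=1, sequence=seq, product=name, domains=list(doms)))
        pos += len(seq) + 50
    region = BGCRegion(
        region_id="MRG_r1", genome_accession="MRG", contig_id="MRG.1",
        start=50, end=pos, product_class="NRPS", genes=genes)
    return region, panels
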