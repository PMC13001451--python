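"""Seeded generators for every input the unmasking pipeline consumes.

The generators emulate the data regime the pipeline is designed for:
ortholog families sharing one short chaperone-like domain — an invariant
KY dipeptide anchor, hydrophobic positions spaced 2–4 apart across a
~25-residue helix, and an acidic/short-hydrophobic alternation over a
~10-residue strand — embedded in rapidly diverging, length-variable polar
flanks; decoy proteomes for calibration and false-discovery checks;
stepping-stone clade layouts; codon alignments with known per-site omega
classes; and toy backbone structures.

Every generator is a pure function of its configuration and seed: repeated
calls are byte-identical, and ground-truth labels are returned alongside
every dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._codon import SENSE_CODONS, CodonRates, f3x4_frequencies
from ._matrices import background_frequencies
from .domain_features import HYDROPHOBIC
from .evol_phylo import CodonAlignment, Tree
from .seqio import AMINO_ACIDS, Residue, SequenceRecord, StructureModel

POLAR_COMPOSITION = {
    # polar/disorder-biased flank composition (unstructured linker regime)
    "S": 0.12, "T": 0.07, "N": 0.06, "Q": 0.06, "E": 0.10, "D": 0.08,
    "K": 0.09, "R": 0.07, "P": 0.09, "G": 0.09, "A": 0.08, "H": 0.02,
    "L": 0.03, "I": 0.01, "V": 0.02, "M": 0.01, "F": 0.00, "W": 0.00,
    "Y": 0.00, "C": 0.00,
}


@dataclass
class DomainArchitecture:
    """Ground-truth layout of the conserved domain inside each protein.

    ``site_rate_multipliers`` has one entry per domain position; anchor
    positions are 0 (invariant) by construction. ``hydrophobic_constraint_sites``
    are positions whose substitutions are restricted to the hydrophobic set.
    """

    domain_length: int = 35
    anchor_offset: int = 23                       # K at 23, Y at 24
    site_rate_multipliers: np.ndarray = None
    hydrophobic_constraint_sites: tuple = (2, 5, 8, 11, 14, 17, 20)
    flank_length_mean: float = 60.0
    flank_length_sd: float = 15.0
    flank_rate_multiplier: float = 4.0
    indel_rate: float = 0.02                      # events per flank site per subst/site

    def __post_init__(self):
        if self.site_rate_multipliers is None:
            m = np.full(self.domain_length, 0.45)
            m[list(self.hydrophobic_constraint_sites)] = 0.3
            # strand alternation positions evolve slowly too
            for k in range(self.anchor_offset + 2, self.domain_length):
                m[k] = 0.35
            m[self.anchor_offset] = 0.0
            m[self.anchor_offset + 1] = 0.0
            self.site_rate_multipliers = m
        assert self.site_rate_multipliers[self.anchor_offset] == 0
        assert self.site_rate_multipliers[self.anchor_offset + 1] == 0

    def ancestral_domain(self, rng: np.random.Generator) -> str:
        """Draw an ancestral domain realizing the three signatures."""
        hydro = sorted(HYDROPHOBIC)
        acidic = "ED"
        short_h = "ILV"
        bg = background_frequencies()
        seq = []
        for k in range(self.domain_length):
            if k == self.anchor_offset:
                seq.append("K")
            elif k == self.anchor_offset + 1:
                seq.append("Y")
            elif k in self.hydrophobic_constraint_sites:
                seq.append(hydro[int(rng.integers(len(hydro)))])
            elif k > self.anchor_offset + 1:
                off = k - (self.anchor_offset + 2)
                pool = acidic if off % 2 == 0 else short_h
                seq.append(pool[int(rng.integers(len(pool)))])
            else:
                seq.append(AMINO_ACIDS[int(rng.choice(20, p=bg))])
        return "".join(seq)


@dataclass
class SimulationConfig:
    """One simulation's full recipe; the seed is mandatory."""

    tree: Tree
    seed: int
    model: str = "protein"                 # "protein" | "codon"
    n_sites: int = 300                     # codon model: number of codons
    kappa: float = 2.0
    omega_classes: tuple = ((1.0, 0.2),)   # (proportion, omega) pairs
    scenario: str = ""

    def __post_init__(self):
        if self.model == "codon":
            total = sum(p for p, _ in self.omega_classes)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("omega class proportions must sum to 1")


# ---------------------------------------------------------------------------
# Protein families
# ---------------------------------------------------------------------------

def _f81_substitute(residues: list, rates: np.ndarray, t: float,
                    bg: np.ndarray, constrained: dict, rng) -> list:
    """Per-site F81-style substitution over the branch: a site changes with
    probability 1 - exp(-beta r t) and redraws from the background (or its
    constrained renormalization)."""
    beta = 1.0 / (1.0 - float(bg @ bg))
    out = list(residues)
    p_change = 1.0 - np.exp(-beta * rates * t)
    draws = rng.random(len(out))
    for i in np.nonzero(draws < p_change)[0]:
        pool = constrained.get(i)
        if pool is None:
            out[i] = AMINO_ACIDS[int(rng.choice(20, p=bg))]
        else:
            letters, probs = pool
            out[i] = letters[int(rng.choice(len(letters), p=probs))]
    return out


def _apply_indels(flank: list, t: float, rate: float, rng) -> list:
    out = list(flank)
    n_events = rng.poisson(rate * t * max(len(out), 1))
    comp_letters = list(POLAR_COMPOSITION)
    comp_probs = np.array(list(POLAR_COMPOSITION.values()))
    comp_probs = comp_probs / comp_probs.sum()
    for _ in range(n_events):
        length = 1 + int(rng.geometric(0.4)) - 1
        if rng.random() < 0.5 and len(out) > length + 2:
            pos = int(rng.integers(0, len(out) - length))
            del out[pos:pos + length]
        else:
            pos = int(rng.integers(0, len(out) + 1))
            ins = [comp_letters[int(rng.choice(len(comp_letters), p=comp_probs))]
                   for _ in range(length)]
            out[pos:pos] = ins
    return out


def _draw_flank(length: int, rng) -> list:
    letters = list(POLAR_COMPOSITION)
    probs = np.array(list(POLAR_COMPOSITION.values()))
    probs = probs / probs.sum()
    return [letters[int(rng.choice(len(letters), p=probs))] for _ in range(length)]


def simulate_protein_family(config: SimulationConfig,
                            architecture: DomainArchitecture | None = None
                            ) -> tuple[list, dict]:
    """Evolve a domain-bearing protein family down the configured tree.

    The domain evolves by site-specific rate multipliers with no indels
    (anchor positions invariant); flanks evolve at
    ``flank_rate_multiplier`` with seeded insertions/deletions, so leaf
    proteins are length-variable and share only the domain. Returns the
    leaf records and a ground-truth map of 0-based half-open domain
    coordinates per leaf.
    """
    arch = architecture or DomainArchitecture()
    rng = np.random.default_rng(config.seed)
    bg = background_frequencies()
    constrained = {}
    hydro = sorted(HYDROPHOBIC)
    hprobs = bg[[AMINO_ACIDS.index(a) for a in hydro]]
    hprobs = hprobs / hprobs.sum()
    for i in arch.hydrophobic_constraint_sites:
        constrained[i] = (hydro, hprobs)

    domain0 = list(arch.ancestral_domain(rng))
    left0 = _draw_flank(max(5, int(rng.normal(arch.flank_length_mean,
                                              arch.flank_length_sd))), rng)
    right0 = _draw_flank(max(5, int(rng.normal(arch.flank_length_mean,
                                               arch.flank_length_sd))), rng)
    frate = arch.flank_rate_multiplier
    records: list[SequenceRecord] = []
    truth: dict[str, tuple[int, int]] = {}

    def walk(node, domain, left, right):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            d = _f81_substitute(domain, arch.site_rate_multipliers, t, bg,
                                constrained, rng)
            lf = _f81_substitute(left, np.full(len(left), frate), t, bg, {}, rng)
            rf = _f81_substitute(right, np.full(len(right), frate), t, bg, {}, rng)
            lf = _apply_indels(lf, t, arch.indel_rate, rng)
            rf = _apply_indels(rf, t, arch.indel_rate, rng)
            if child.is_leaf():
                name = child.taxon.label
                seq = "".join(lf) + "".join(d) + "".join(rf)
                records.append(SequenceRecord(name, seq, "protein"))
                truth[name] = (len(lf), len(lf) + len(d))
            else:
                walk(child, d, lf, rf)

    root = config.tree.dendropy_tree.seed_node
    walk(root, domain0, left0, right0)
    return records, truth


# ---------------------------------------------------------------------------
# Stepping-stone clade scenario
# ---------------------------------------------------------------------------

@dataclass
class SteppingStoneDataset:
    seed_records: list            # clade A (the well-annotated seeds)
    intermediate: SequenceRecord  # clade C, at intermediate divergence
    remote: SequenceRecord        # clade B, the distant target
    decoys: list
    truth: dict                   # id -> (domain_start, domain_end)
    tree: Tree

    def seed_domain_alignment(self):
        """Trimmed seed alignment: the A-clade domain regions (the domain
        evolves without indels, so the rows align column-for-column)."""
        from .seqio import Alignment
        rows = [(r.id, r.residues[self.truth[r.id][0]:self.truth[r.id][1]])
                for r in self.seed_records]
        return Alignment(rows)


def stepping_stone_scenario(divergence_ab: float = 3.2,
                            divergence_intermediate: float = 1.2,
                            n_decoys: int = 100,
                            n_seed: int = 4,
                            seed: int = 11) -> SteppingStoneDataset:
    """Three-clade layout testing the evolutionary-intermediate strategy.

    Clade A (``n_seed`` closely related sequences) sits ``divergence_ab``
    expected substitutions/site from the remote ortholog B; the
    intermediate C branches off the A-B path at ``divergence_intermediate``
    from A (so C is ``divergence_ab - divergence_intermediate`` from B).
    Decoys are composition-matched to the family. At the default
    divergences, a profile from A alone should miss B while a profile that
    has admitted C should reach it.
    """
    if not divergence_intermediate < divergence_ab:
        raise ValueError("intermediate must be closer than the remote clade")
    d_int = divergence_intermediate
    a_spread = min(0.15, d_int / 3.0)
    c_stem = min(0.1, (divergence_ab - d_int) / 3.0)
    inner = ",".join(f"A{i}:{a_spread}" for i in range(n_seed))
    # root placed at C's attachment point on the A-B path
    newick = (f"(({inner}):{d_int - a_spread:.6f},C:{c_stem:.6f},"
              f"B:{divergence_ab - d_int - c_stem:.6f});")
    tree = Tree.from_newick(newick)
    config = SimulationConfig(tree=tree, seed=seed, model="protein",
                              scenario="stepping_stone")
    records, truth = simulate_protein_family(config)
    by_id = {r.id: r for r in records}
    seeds = [by_id[f"A{i}"] for i in range(n_seed)]
    family_comp = np.zeros(20)
    for r in records:
        for ch in r.residues:
            if ch in AMINO_ACIDS:
                family_comp[AMINO_ACIDS.index(ch)] += 1
    family_comp /= family_comp.sum()
    lengths = [len(r.residues) for r in records]
    decoys = make_decoy_proteome(
        n_decoys, (float(np.mean(lengths)), float(np.std(lengths) + 1)),
        family_comp, seed=seed + 7919)
    return SteppingStoneDataset(seeds, by_id["C"], by_id["B"], decoys,
                                truth, tree)


# ---------------------------------------------------------------------------
# Codon families
# ---------------------------------------------------------------------------

def simulate_codon_family(config: SimulationConfig
                          ) -> tuple[CodonAlignment, np.ndarray]:
    """GY94 simulation along the tree with per-site omega classes.

    Ancestral codons are drawn from the stationary distribution; branch
    lengths are expected substitutions per codon site. Returns the leaf
    codon alignment (no gaps) and the true class index per site.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    props = np.array([p for p, _ in config.omega_classes])
    omegas = [w for _, w in config.omega_classes]
    pi = np.full(61, 1.0 / 61)
    classes = rng.choice(len(omegas), size=n, p=props)
    rates = [CodonRates.from_parameters(config.kappa, w, pi) for w in omegas]
    ancestral = rng.choice(61, size=n, p=pi)

    rows = []

    def walk(node, states):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            new = states.copy()
            for ci, rt in enumerate(rates):
                sites = np.nonzero(classes == ci)[0]
                if not len(sites):
                    continue
                P = rt.transition_matrix(t)
                P = P / P.sum(axis=1, keepdims=True)
                for s in sites:
                    new[s] = rng.choice(61, p=P[states[s]])
            if child.is_leaf():
                seq = "".join(SENSE_CODONS[k] for k in new)
                rows.append((child.taxon.label, seq))
            else:
                walk(child, new)

    walk(config.tree.dendropy_tree.seed_node, ancestral)
    return CodonAlignment(rows), classes


# ---------------------------------------------------------------------------
# Decoys and toy structures
# ---------------------------------------------------------------------------

def make_decoy_proteome(n: int, length_distribution: tuple,
                        composition: np.ndarray | None = None,
                        seed: int = 0) -> list:
    """I.i.d. decoy proteins with the given residue composition and a
    normal length law (mean, sd), ids namespaced ``decoy_``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if composition is None:
        composition = background_frequencies()
    composition = np.asarray(composition, dtype=float)
    composition = composition / composition.sum()
    mean, sd = length_distribution
    out = []
    for i in range(n):
        length = max(10, int(rng.normal(mean, sd)))
        idx = rng.choice(20, size=length, p=composition)
        out.append(SequenceRecord(f"decoy_{i}",
                                  "".join(AMINO_ACIDS[k] for k in idx),
                                  "protein"))
    return out


_HELIX_RISE = 1.5          # Å per residue along the axis
_HELIX_TWIST = math.radians(100.0)
_HELIX_RADIUS = 2.3


def _backbone_residue(number: int, ca: np.ndarray, tangent: np.ndarray,
                      confidence: float) -> Residue:
    """Plant N/C/O around a CA along the local chain direction; idealized
    spacing, good enough for superposition and contact geometry."""
    tangent = tangent / np.linalg.norm(tangent)
    ortho = np.cross(tangent, [0.0, 0.0, 1.0])
    if np.linalg.norm(ortho) < 1e-6:
        ortho = np.cross(tangent, [0.0, 1.0, 0.0])
    ortho = ortho / np.linalg.norm(ortho)
    atoms = {
        "N": ca - 1.46 * tangent,
        "CA": ca,
        "C": ca + 1.52 * tangent,
        "O": ca + 1.52 * tangent + 1.23 * ortho,
    }
    return Residue(number, "ALA", atoms, confidence)


def make_toy_structures(kind: str = "ideal_helix", n_residues: int = 25,
                        sigma: float = 0.0, seed: int = 0,
                        template: StructureModel | None = None,
                        chain_id: str = "A",
                        confidence: float = 90.0) -> StructureModel:
    """Idealized backbone traces for structural-validation tests.

    Kinds: ``ideal_helix`` (1.5 Å rise, 100° twist — consecutive CA–CA
    ≈ 3.8 Å), ``helix_plus_strand`` (25-residue helix then extended strand),
    ``noisy_copy`` (template plus isotropic Gaussian displacement of
    standard deviation ``sigma``).
    """
    if kind == "noisy_copy":
        if template is None:
            raise ValueError("noisy_copy requires a template")
        rng = np.random.default_rng(seed)
        residues = []
        for r in template.residues:
            atoms = {name: xyz + rng.normal(0.0, sigma, 3)
                     for name, xyz in r.atoms.items()}
            residues.append(Residue(r.number, r.name, atoms, r.confidence))
        return StructureModel(template.chain_id, residues)

    cas: list[np.ndarray] = []
    if kind == "ideal_helix":
        for i in range(n_residues):
            ang = i * _HELIX_TWIST
            cas.append(np.array([_HELIX_RADIUS * math.cos(ang),
                                 _HELIX_RADIUS * math.sin(ang),
                                 _HELIX_RISE * i]))
    elif kind == "helix_plus_strand":
        n_helix, n_strand = 25, 10
        for i in range(n_helix):
            ang = i * _HELIX_TWIST
            cas.append(np.array([_HELIX_RADIUS * math.cos(ang),
                                 _HELIX_RADIUS * math.sin(ang),
                                 _HELIX_RISE * i]))
        start = cas[-1]
        direction = np.array([1.0, 0.5, 0.2])
        direction /= np.linalg.norm(direction)
        for i in range(1, n_strand + 1):
            cas.append(start + 3.5 * i * direction)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    residues = []
    for i, ca in enumerate(cas):
        nxt = cas[i + 1] if i + 1 < len(cas) else cas[i] + (cas[i] - cas[i - 1])
        tangent = nxt - ca
        residues.append(_backbone_residue(i + 1, ca, tangent, confidence))
    return StructureModel(chain_id, residues)
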