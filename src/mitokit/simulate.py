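"""Synthetic mitogenome generator.

Generates fully annotated circular mitogenomes and aligned per-gene
datasets with the statistical structure the analysis pipeline assumes:

* a Yule (pure-birth) taxon tree with a designated outgroup and an
  optional planted clade carrying derived tRNA rearrangements;
* GTR+Gamma+I sequence evolution with per-gene and per-codon-position
  rate multipliers (third positions fast enough to saturate, a trio of
  analogues of the fast atp8/nad4l/nad6 genes elevated);
* AT-rich, strand-asymmetric stationary frequencies (coding sense), so
  realized composition matches typical sawfly mitogenomes (AT ~ 0.82,
  protein-coding AT skew ~ -0.11);
* in-frame protein-coding genes with ATN starts, no internal stops
  (codon-level rejection), and complete (TAA) or planted partial (T- /
  TA-) stop codons;
* per-taxon genome assembly on the ring with random intergenic spacers
  and an A+T-rich control region, emitted as GenBank / FASTA / feature
  tables.

All randomness flows from one integer seed through named substreams, so a
fixed seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .alphabet import ANCESTRAL_ARRANGEMENT, CONTROL_REGION, PCGS, RRNAS, TRNAS
from .gene_order import GeneOrder, ancestral_pancrustacean_order, derived_megabelesesinae_order
from .records import GeneAnnotation, MitogenomeRecord, reverse_complement
from .saturation import SubstitutionModel, _eigen, gamma_category_rates

_BASES = "ACGT"
_STOPS = ("TAA", "TAG")

#: realistic per-gene core codon counts (start and stop codons excluded)
PCG_CORE_CODONS: dict[str, int] = {
    "cox1": 511, "cox2": 226, "cox3": 261, "cob": 378,
    "nad1": 311, "nad2": 341, "nad3": 116, "nad4": 446,
    "nad4l": 96, "nad5": 572, "nad6": 171, "atp6": 225, "atp8": 52,
}

RRNA_LENGTHS: dict[str, int] = {"rrnL": 1300, "rrnS": 780}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the generator.

    Frequencies are coding-sense stationary distributions per gene class
    and strand; ``tree_depth`` is the root-to-tip length in expected
    substitutions/site at relative rate 1.  ``length_scale`` shrinks gene
    lengths proportionally for fast runs without changing the process.
    """

    n_taxa: int = 20
    seed: int = 1
    birth_rate: float = 1.0
    tree_depth: float = 0.3
    outgroup: bool = True
    clade_size: int = 4
    clade_prefix: str = "clade"
    plant_rearrangements: bool = True
    length_scale: float = 1.0
    # GTR+G+I shared across partitions (frequencies vary by class/strand)
    exchangeabilities: tuple[float, ...] = (1.5, 8.0, 1.5, 1.0, 10.0, 1.0)
    alpha: float = 0.5
    p_inv: float = 0.15
    gamma_k: int = 4
    # coding-sense stationary frequencies (A, C, G, T); the N-strand PCGs
    # are more T-rich in coding sense, so the forward-strand genome ends up
    # mildly A-skewed while the pooled PCG partition is T-skewed (~ -0.11
    # after stop-codon rejection shifts realized skews slightly T-ward)
    pcg_freqs_j: tuple[float, ...] = (0.3892, 0.0910, 0.0940, 0.4258)
    pcg_freqs_n: tuple[float, ...] = (0.3647, 0.0900, 0.0950, 0.4503)
    rna_freqs_j: tuple[float, ...] = (0.440, 0.0750, 0.0750, 0.410)
    rna_freqs_n: tuple[float, ...] = (0.410, 0.0700, 0.0800, 0.440)
    at_rich_freqs: tuple[float, ...] = (0.485, 0.0400, 0.0400, 0.435)
    # rate structure
    position_multipliers: tuple[float, float, float] = (1.0, 0.6, 20.0)
    elevated_genes: tuple[str, ...] = ("atp8", "nad4l", "nad6")
    elevated_multiplier: float = 2.5
    rna_multiplier: float = 0.8
    # architecture
    at_rich_length_range: tuple[int, int] = (600, 1000)
    spacer_length_range: tuple[int, int] = (0, 12)
    spacer_zero_prob: float = 0.5
    trna_length_range: tuple[int, int] = (60, 71)
    partial_stop_genes: dict = field(
        default_factory=lambda: {"cob": "T", "nad4": "TA"}
    )

    def substream(self, index: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, index]))

    def gene_multiplier(self, gene: str) -> float:
        if gene in PCGS:
            base = self.elevated_multiplier if gene in self.elevated_genes else 1.0
            return base
        return self.rna_multiplier


def _freqs_for(config: SimulationConfig, gene: str, strand: str) -> np.ndarray:
    if gene in PCGS:
        f = config.pcg_freqs_j if strand == "J" else config.pcg_freqs_n
    else:
        f = config.rna_freqs_j if strand == "J" else config.rna_freqs_n
    return np.asarray(f)


def simulate_tree(config: SimulationConfig) -> dendropy.Tree:
    """Yule tree with n_taxa ingroup leaves scaled to the requested depth.

    When a planted clade is configured, one backbone leaf is expanded into
    a short clade subtree (leaves named ``<clade_prefix>1..k``); the
    outgroup attaches below a new root with a long pendant branch.
    Deterministic under the seed.
    """
    if config.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    import random as _random

    rng = _random.Random(int(config.substream(0).integers(0, 2**31)))
    clade_k = config.clade_size if config.clade_size >= 2 else 0
    n_backbone = config.n_taxa - max(clade_k - 1, 0)
    if n_backbone < 3:
        raise ValueError(
            f"n_taxa={config.n_taxa} leaves only {n_backbone} backbone lineages "
            f"after planting a {clade_k}-taxon clade; need at least 3"
        )
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=n_backbone,
        rng=rng,
        repeat_until_success=True,
    )
    # scale to requested root-to-tip depth
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= config.tree_depth / depth
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    for i, leaf in enumerate(leaves):
        leaf.taxon.label = f"t{i + 1:02d}"

    if clade_k:
        host = leaves[rng.randrange(len(leaves))]
        sub = treesim.birth_death_tree(
            birth_rate=config.birth_rate,
            death_rate=0.0,
            num_extant_tips=clade_k,
            rng=rng,
            repeat_until_success=True,
        )
        sub_depth = max(leaf.distance_from_root() for leaf in sub.leaf_node_iter())
        target_depth = min(host.edge.length * 0.5, config.tree_depth * 0.25)
        for edge in sub.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= target_depth / sub_depth
        for i, leaf in enumerate(
            sorted(sub.leaf_node_iter(), key=lambda nd: nd.taxon.label)
        ):
            leaf.taxon.label = f"{config.clade_prefix}{i + 1}"
        host.edge.length -= target_depth
        graft = sub.seed_node
        graft.edge.length = 0.0
        host.add_child(graft)
        host.taxon = None  # host becomes internal
        tree.suppress_unifurcations()

    if config.outgroup:
        old_root = tree.seed_node
        new_root = dendropy.Node()
        tree.seed_node = new_root
        new_root.add_child(old_root)
        old_root.edge.length = config.tree_depth * 0.3
        og = dendropy.Node()
        og.edge.length = config.tree_depth * 1.3
        new_root.add_child(og)
        og.taxon = dendropy.Taxon(label="outgroup")
        tree.taxon_namespace.add_taxon(og.taxon)
    tree.update_taxon_namespace()
    tree.purge_taxon_namespace()
    return tree


def _sample_states(P: np.ndarray, parents: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = P.cumsum(axis=1)
    u = rng.random(parents.shape[0])
    return np.minimum((u[:, None] > cum[parents]).sum(axis=1), 3).astype(np.int8)


def _evolve_states(
    tree: dendropy.Tree,
    root_states: np.ndarray,
    site_rates: np.ndarray,
    eig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Evolve site states down the tree; site_rates of 0 are invariant."""
    uniq = np.unique(site_rates)
    groups = {r: np.where(site_rates == r)[0] for r in uniq}
    states = {id(tree.seed_node): root_states}
    leaves: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            s = root_states
        else:
            parent = states[id(node.parent_node)]
            s = parent.copy()
            t = node.edge.length or 0.0
            for r, idx in groups.items():
                if r == 0.0 or t == 0.0 or len(idx) == 0:
                    continue
                P = eig.right @ (np.exp(eig.lam * r * t)[:, None] * eig.left)
                P = np.clip(P, 0.0, None)
                P /= P.sum(axis=1, keepdims=True)
                s[idx] = _sample_states(P, parent[idx], rng)
        states[id(node)] = s
        if node.is_leaf():
            leaves[node.taxon.label] = s
    return leaves


def _decode(states: np.ndarray) -> str:
    return "".join(_BASES[i] for i in states)


def _draw_site_rates(
    n_sites: int,
    base_multiplier: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    cat_rates = gamma_category_rates(config.alpha, config.gamma_k)
    cats = rng.integers(0, config.gamma_k, size=n_sites)
    rates = cat_rates[cats] * base_multiplier
    invariant = rng.random(n_sites) < config.p_inv
    rates[invariant] = 0.0
    return rates


def _sample_root_codons(n_codons: int, freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    states = rng.choice(4, size=3 * n_codons, p=freqs)
    while True:
        codons = states.reshape(-1, 3)
        bad = np.where(
            (codons[:, 0] == 3) & (codons[:, 1] == 0) & np.isin(codons[:, 2], (0, 2))
        )[0]
        if len(bad) == 0:
            return states
        for i in bad:
            states[3 * i : 3 * i + 3] = rng.choice(4, size=3, p=freqs)


def _has_internal_stop(mat: np.ndarray) -> np.ndarray:
    """Boolean per codon column: any taxon carries TAA/TAG."""
    cod = mat.reshape(mat.shape[0], -1, 3)
    return ((cod[:, :, 0] == 3) & (cod[:, :, 1] == 0) & np.isin(cod[:, :, 2], (0, 2))).any(axis=0)


def evolve_genes(tree: dendropy.Tree, config: SimulationConfig) -> dict[str, dict[str, str]]:
    """Aligned (ungapped) coding-sense sequences for all 37 genes.

    PCGs are generated in frame with a fixed ATN start, a rejection-sampled
    stop-free core, and a TAA or planted partial stop; RNAs evolve as plain
    nucleotide tracts.  Deterministic under the config seed.
    """
    rng = config.substream(1)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    strand_of = dict(ANCESTRAL_ARRANGEMENT)
    model_cache: dict[tuple, object] = {}
    out: dict[str, dict[str, str]] = {}

    def eig_for(freqs: np.ndarray):
        key = tuple(np.round(freqs, 6))
        if key not in model_cache:
            model = SubstitutionModel(
                pi=tuple(freqs / freqs.sum()),
                exchangeabilities=config.exchangeabilities,
                alpha=config.alpha,
                p_inv=config.p_inv,
                k=config.gamma_k,
            )
            model_cache[key] = _eigen(model)
        return model_cache[key]

    for gene in PCGS:
        freqs = _freqs_for(config, gene, strand_of[gene])
        eig = eig_for(freqs)
        n_codons = max(10, round(PCG_CORE_CODONS[gene] * config.length_scale))
        gmult = config.gene_multiplier(gene)
        pos_mult = np.tile(np.asarray(config.position_multipliers) * gmult, n_codons)
        rates = _draw_site_rates(3 * n_codons, pos_mult, config, rng)
        root = _sample_root_codons(n_codons, freqs, rng)
        leaves = _evolve_states(tree, root, rates, eig, rng)
        mat = np.stack([leaves[t] for t in taxa])
        for _ in range(200):
            bad = np.where(_has_internal_stop(mat))[0]
            if len(bad) == 0:
                break
            site_idx = np.concatenate([np.arange(3 * i, 3 * i + 3) for i in bad])
            sub_root = _sample_root_codons(len(bad), freqs, rng)
            sub_leaves = _evolve_states(tree, sub_root, rates[site_idx], eig, rng)
            for ti, t in enumerate(taxa):
                mat[ti, site_idx] = sub_leaves[t]
        start = rng.choice(["ATG", "ATA", "ATT"])
        stop = config.partial_stop_genes.get(gene, "TAA")
        out[gene] = {t: start + _decode(mat[ti]) + stop for ti, t in enumerate(taxa)}

    for gene in TRNAS + RRNAS:
        freqs = _freqs_for(config, gene, strand_of[gene])
        eig = eig_for(freqs)
        if gene in RRNAS:
            length = max(60, round(RRNA_LENGTHS[gene] * config.length_scale))
        else:
            lo, hi = config.trna_length_range
            length = int(rng.integers(lo, hi + 1))
        rates = _draw_site_rates(length, np.full(length, config.gene_multiplier(gene)), config, rng)
        root = rng.choice(4, size=length, p=freqs / freqs.sum()).astype(np.int8)
        leaves = _evolve_states(tree, root, rates, eig, rng)
        out[gene] = {t: _decode(leaves[t]) for t in taxa}
    return out


def simulate_alignment(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    length: int,
    seed: int,
    multiplier: float = 1.0,
) -> dict[str, str]:
    """Evolve a plain (non-coding) alignment of *length* sites under a
    GTR+Gamma+I model along *tree*; branch lengths are multiplied by
    *multiplier*.  Site rates are drawn per site (gamma category or
    invariant), matching the model used by the distance machinery."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    eig = _eigen(model)
    cat_rates = gamma_category_rates(model.alpha, model.k)
    cats = rng.integers(0, model.k, size=length)
    rates = cat_rates[cats] * multiplier
    rates[rng.random(length) < model.p_inv] = 0.0
    pi = np.asarray(model.pi)
    root = rng.choice(4, size=length, p=pi / pi.sum()).astype(np.int8)
    leaves = _evolve_states(tree, root, rates, eig, rng)
    return {t: _decode(s) for t, s in leaves.items()}


def simulate_pair(
    model: SubstitutionModel, distance: float, length: int, seed: int
) -> tuple[str, str]:
    """Two sequences separated by *distance* expected substitutions/site."""
    tree = dendropy.Tree.get(
        data=f"(a:{distance / 2:.8f},b:{distance / 2:.8f});", schema="newick"
    )
    aln = simulate_alignment(tree, model, length, seed)
    return aln["a"], aln["b"]


def _random_seq(length: int, freqs: np.ndarray, rng: np.random.Generator) -> str:
    return _decode(rng.choice(4, size=length, p=freqs / freqs.sum()))


def emit_mitogenomes(
    tree: dendropy.Tree,
    gene_seqs: dict[str, dict[str, str]],
    config: SimulationConfig,
    outdir: str | Path | None = None,
) -> list[MitogenomeRecord]:
    """Assemble one circular annotated genome per taxon.

    Genes are laid on the ring in the ancestral arrangement; members of the
    planted clade instead receive the derived arrangement (MQI + ANS1ERF
    states).  Intergenic spacers and the A+T-rich region are drawn from the
    configured ranges.  With *outdir*, GenBank, FASTA + feature-table and
    per-gene aligned FASTA files are written.
    """
    rng = config.substream(2)
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    clade_taxa = {t for t in taxa if t.startswith(config.clade_prefix)}
    if config.plant_rearrangements and config.clade_size >= 2 and not clade_taxa:
        raise ValueError(
            f"planted rearrangements reference clade prefix {config.clade_prefix!r} "
            "but no leaf matches it"
        )
    ancestral = ancestral_pancrustacean_order()
    derived = derived_megabelesesinae_order()
    atrich_freqs = np.asarray(config.at_rich_freqs)
    records = []
    for taxon in taxa:
        use_derived = config.plant_rearrangements and taxon in clade_taxa
        order: GeneOrder = derived if use_derived else ancestral
        seq_parts: list[str] = []
        anns: list[GeneAnnotation] = []
        pos = 0
        lo, hi = config.spacer_length_range

        def add_spacer() -> None:
            nonlocal pos
            if hi <= lo:
                n = lo
            elif rng.random() < config.spacer_zero_prob:
                n = 0
            else:
                n = int(rng.integers(max(lo, 1), hi + 1))
            if n > 0:
                seq_parts.append(_random_seq(n, atrich_freqs, rng))
                pos += n

        for gene, sign in order.order:
            coding = gene_seqs[gene][taxon]
            genomic = coding if sign > 0 else reverse_complement(coding)
            anns.append(
                GeneAnnotation(
                    name=gene,
                    start=pos,
                    end=pos + len(genomic),
                    strand="J" if sign > 0 else "N",
                )
            )
            seq_parts.append(genomic)
            pos += len(genomic)
            if gene == "rrnS":
                add_spacer()
                alo, ahi = config.at_rich_length_range
                alen = int(rng.integers(alo, ahi + 1)) if ahi > alo else alo
                alen = max(50, round(alen * config.length_scale))
                anns.append(
                    GeneAnnotation(name=CONTROL_REGION, start=pos, end=pos + alen, strand="J")
                )
                seq_parts.append(_random_seq(alen, atrich_freqs, rng))
                pos += alen
            add_spacer()
        records.append(
            MitogenomeRecord(taxon=taxon, sequence="".join(seq_parts), annotations=anns)
        )
    if outdir is not None:
        _write_outputs(records, gene_seqs, config, Path(outdir))
    return records


def _write_outputs(
    records: list[MitogenomeRecord],
    gene_seqs: dict[str, dict[str, str]],
    config: SimulationConfig,
    outdir: Path,
) -> None:
    from . import io as mio
    from .dataset import write_fasta_alignment

    outdir.mkdir(parents=True, exist_ok=True)
    gb = outdir / "genbank"
    gb.mkdir(exist_ok=True)
    for rec in records:
        mio.write_genbank(rec, gb / f"{rec.taxon}.gb")
        mio.write_feature_table(rec, gb / f"{rec.taxon}.fasta", gb / f"{rec.taxon}.tbl")
    genes_dir = outdir / "genes"
    genes_dir.mkdir(exist_ok=True)
    for gene, aln in gene_seqs.items():
        write_fasta_alignment(aln, genes_dir / f"{gene}.fasta")
    manifest = {
        "seed": config.seed,
        "n_taxa": config.n_taxa,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    import yaml

    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    tree: dendropy.Tree
    gene_alignments: dict[str, dict[str, str]]
    records: list[MitogenomeRecord]
    clade_taxa: set[str]
    outgroup_taxon: str | None


def simulate_dataset(config: SimulationConfig, outdir: str | Path | None = None) -> SimulatedDataset:
    """Run the three generator stages end to end."""
    tree = simulate_tree(config)
    genes = evolve_genes(tree, config)
    records = emit_mitogenomes(tree, genes, config, outdir=outdir)
    taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    return SimulatedDataset(
        config=config,
        tree=tree,
        gene_alignments=genes,
        records=records,
        clade_taxa={t for t in taxa if t.startswith(config.clade_prefix)},
        outgroup_taxon="outgroup" if config.outgroup else None,
    )
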