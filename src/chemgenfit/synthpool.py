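"""Synthetic pooled-competition bar-seq data with known ground truth.

Emulates a chemical-genomics screen of a barcoded deletion library: a pool
of ~4309 uniquely barcoded strains grown competitively for 6.5-10 population
doublings in each of a panel of inhibitors alongside in-plate paired
controls, in biological triplicate, followed by amplicon sequencing of the
up-tag barcodes. Every generator is deterministic for a fixed seed and emits
the planted truth next to the data so downstream stages can be scored.

The competition model is deliberately simple: expected strain frequencies
propagate deterministically as ``f_g * 2**(G * s_gc)`` (selection coefficient
``s`` per doubling, ``G`` doublings) and all stochasticity enters at the
sequencing step through gamma-Poisson (negative-binomial) read sampling.
This keeps closed-form expectations available for oracle tests.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

GENE_CLASSES = ("neutral", "beneficial-only", "deleterious-only", "antagonistic")


@dataclass
class TruthConfig:
    """Effect-model parameters for planted per-gene x compound fitness.

    fractions: proportion of genes in each class (must sum to 1).
    effect_low/effect_high: |s| drawn uniformly per gene x compound-class,
        in log2 units per doubling.
    n_compound_classes: compounds are partitioned into this many classes;
        compounds of a class share each gene's class-level effect up to a
        multiplicative jitter, which enforces correlated truth columns.
    class_affect_prob: probability a non-neutral gene carries an effect in
        any given compound class (at least one class is always affected;
        antagonistic genes always affect >= 2 classes with mixed signs).
    within_class_jitter: half-width of the multiplicative U[1-j, 1+j] noise
        applied per compound around the class-level effect.
    dispersion: per-gene NB overdispersion used at the sequencing step.
    """

    fractions: dict = field(default_factory=lambda: {
        "neutral": 0.70, "beneficial-only": 0.10,
        "deleterious-only": 0.10, "antagonistic": 0.10})
    effect_low: float = 0.1
    effect_high: float = 0.5
    n_compound_classes: int = 2
    class_affect_prob: float = 0.7
    within_class_jitter: float = 0.15
    dispersion: float = 0.05


@dataclass
class SimulationTruth:
    """Planted ground truth emitted alongside each synthetic dataset."""

    s: pd.DataFrame                # genes x compounds, log2 per doubling
    gene_class: pd.Series          # gene -> class label
    compound_class: pd.Series      # compound -> integer class label
    dispersion: pd.Series          # gene -> NB dispersion
    effect_floor: float            # smallest planted |s| after jitter
    seed: int

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        self.s.to_csv(outdir / "truth_s.tsv", sep="\t", index_label="gene")
        pd.DataFrame({"gene_class": self.gene_class}).to_csv(
            outdir / "truth_gene_class.tsv", sep="\t", index_label="gene")
        pd.DataFrame({"compound_class": self.compound_class}).to_csv(
            outdir / "truth_compound_class.tsv", sep="\t", index_label="compound")


@dataclass
class CountMatrix:
    """Integer up-tag read counts (strains x samples) plus sample metadata."""

    counts: pd.DataFrame
    design: pd.DataFrame

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class ReferenceCompendium:
    """Compound x gene fitness z-scores with compound -> signature-set labels."""

    z: pd.DataFrame                # ref compounds x genes
    set_map: pd.Series             # ref compound -> signature-set name
    planted: pd.DataFrame          # gene, signature_set, sign (truth, for scoring)


# ---------------------------------------------------------------------------


def generate_catalog(n_strains: int, barcode_length: int = 20,
                     seed: int = 0) -> pd.DataFrame:
    """Draw a strain catalog with unique up-tag barcodes.

    One gene per strain, one strain per gene; barcodes are uniform random
    over {A,C,G,T}^L, redrawn on collision.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if barcode_length < 8:
        raise ValueError("barcode_length must be >= 8")
    if 4 ** barcode_length < n_strains:
        raise ValueError("barcode space too small for requested strains")
    rng = np.random.default_rng(seed)
    seen: set[bytes] = set()
    barcodes: list[str] = []
    attempts = 0
    max_attempts = 20 * n_strains + 1000
    while len(barcodes) < n_strains:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not draw {n_strains} unique barcodes of length "
                f"{barcode_length} after {max_attempts} attempts")
        bc = BASES[rng.integers(0, 4, barcode_length)].tobytes()
        if bc in seen:
            continue
        seen.add(bc)
        barcodes.append(bc.decode())
    width = max(4, len(str(n_strains - 1)))
    return pd.DataFrame({
        "strain_id": [f"strain_{i:0{width}d}" for i in range(n_strains)],
        "gene": [f"gene_{i:0{width}d}" for i in range(n_strains)],
        "uptag": barcodes,
    })


def _allocate_classes(n: int, fractions: dict, rng) -> np.ndarray:
    """Largest-remainder allocation of genes to classes, then shuffled."""
    names = list(fractions)
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions sum to {total}, expected 1")
    ideal = np.array([fractions[c] * n for c in names])
    base = np.floor(ideal).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(ideal - base))
    base[order[:rem]] += 1
    labels = np.repeat(names, base)
    return rng.permutation(labels)


def generate_truth(catalog: pd.DataFrame, compounds: list[str],
                   config: TruthConfig | None = None,
                   seed: int = 0) -> SimulationTruth:
    """Plant per-gene x compound selection coefficients with class structure."""
    config = config or TruthConfig()
    rng = np.random.default_rng(seed)
    genes = list(catalog["gene"])
    n_genes, n_comp = len(genes), len(compounds)
    n_classes = max(1, min(config.n_compound_classes, n_comp))
    frac_ant = config.fractions.get("antagonistic", 0.0)
    if frac_ant > 0 and n_classes < 2:
        raise ValueError("antagonistic genes require >= 2 compound classes")

    gene_class = _allocate_classes(n_genes, config.fractions, rng)
    compound_class = np.arange(n_comp) % n_classes

    # class-level effect per gene: sign * |s|, zero where unaffected
    class_effect = np.zeros((n_genes, n_classes))
    for i, cls in enumerate(gene_class):
        if cls == "neutral":
            continue
        affected = rng.random(n_classes) < config.class_affect_prob
        min_affected = 2 if cls == "antagonistic" else 1
        while affected.sum() < min_affected:
            affected[rng.integers(0, n_classes)] = True
        idx = np.flatnonzero(affected)
        mags = rng.uniform(config.effect_low, config.effect_high, idx.size)
        if cls == "beneficial-only":
            signs = np.ones(idx.size)
        elif cls == "deleterious-only":
            signs = -np.ones(idx.size)
        else:  # antagonistic: mixed signs guaranteed
            signs = np.where(rng.random(idx.size) < 0.5, 1.0, -1.0)
            if np.all(signs > 0) or np.all(signs < 0):
                signs[rng.integers(0, idx.size)] *= -1
        class_effect[i, idx] = signs * mags

    jit = config.within_class_jitter
    jitter = 1.0 + rng.uniform(-jit, jit, (n_genes, n_comp))
    s = class_effect[:, compound_class] * jitter
    floor = config.effect_low * (1.0 - jit)
    return SimulationTruth(
        s=pd.DataFrame(s, index=pd.Index(genes, name="gene"), columns=compounds),
        gene_class=pd.Series(gene_class, index=genes, name="gene_class"),
        compound_class=pd.Series(compound_class, index=compounds,
                                 name="compound_class"),
        dispersion=pd.Series(config.dispersion, index=genes, name="dispersion"),
        effect_floor=floor,
        seed=seed,
    )


def generate_design(compounds: list[str], n_replicates: int = 3,
                    unpaired: tuple[str, ...] = (),
                    generations_range: tuple[float, float] = (6.5, 10.0),
                    seed: int = 0) -> pd.DataFrame:
    """Build a treatment/control design with in-plate paired replicates.

    Each paired treatment replicate shares a plate (batch) and a pair id with
    its own control sample; compounds listed in ``unpaired`` get control
    replicates without pair links (analyzed unpaired downstream). The number
    of population doublings is drawn per plate from ``generations_range``.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per compound")
    lo, hi = generations_range
    if not (6.5 - 1e-9 <= lo <= hi <= 10.0 + 1e-9):
        raise ValueError("generations_range must lie within [6.5, 10]")
    rng = np.random.default_rng(seed)
    rows = []
    for comp in compounds:
        paired = comp not in unpaired
        for r in range(1, n_replicates + 1):
            batch = f"plate_{comp}_{r}"
            gens = rng.uniform(lo, hi)
            pair = f"{comp}_p{r}" if paired else None
            rows.append({"sample_id": f"{comp}_ctrl_{r}", "compound": comp,
                         "role": "control", "pair_id": pair, "batch": batch,
                         "replicate": r, "generations": gens})
            rows.append({"sample_id": f"{comp}_trt_{r}", "compound": comp,
                         "role": "treatment", "pair_id": pair, "batch": batch,
                         "replicate": r, "generations": gens})
    return pd.DataFrame(rows)


def simulate_counts(catalog: pd.DataFrame, design: pd.DataFrame,
                    truth: SimulationTruth, depth: int = 2_000_000,
                    seed: int = 0, batch_sigma: float = 0.3,
                    depth_sigma: float = 0.1,
                    initial_freq_sigma: float = 0.25) -> CountMatrix:
    """Sample an up-tag count matrix from planted truth.

    Expected proportions per treatment sample are ``f_g * 2**(G * s_gc)``
    renormalized (``s = 0`` for controls). Members of a replicate pair share
    a gene-wise log-normal batch factor (sigma ``batch_sigma``) and a common
    sequencing depth; reads are gamma-Poisson with the per-gene dispersion
    from the truth.
    """
    if depth < 1000:
        raise ValueError("depth must be >= 1000 reads/sample")
    genes = list(truth.s.index)
    if list(catalog["gene"]) != genes:
        raise ValueError("catalog genes do not match truth genes")
    missing = set(design["compound"]) - set(truth.s.columns)
    if missing:
        raise ValueError(f"design compounds absent from truth: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n_genes = len(genes)

    f0 = np.exp(rng.normal(0.0, initial_freq_sigma, n_genes))
    f0 /= f0.sum()
    phi = truth.dispersion.to_numpy()

    # shared per-pair nuisance draws; unpaired samples get their own
    keys = []
    for _, row in design.iterrows():
        keys.append(row["pair_id"] if pd.notna(row["pair_id"]) else row["sample_id"])
    shared: dict[str, tuple[np.ndarray, float]] = {}
    for key in keys:
        if key not in shared:
            batch = np.exp(rng.normal(0.0, batch_sigma, n_genes))
            d = depth * np.exp(rng.normal(0.0, depth_sigma))
            shared[key] = (batch, d)

    counts = np.zeros((n_genes, len(design)), dtype=np.int64)
    for j, (_, row) in enumerate(design.iterrows()):
        gens = float(row["generations"]) if "generations" in row else 8.0
        if row["role"] == "treatment":
            s = truth.s[row["compound"]].to_numpy()
            p = f0 * np.exp2(gens * s)
        else:
            p = f0.copy()
        batch, d = shared[keys[j]]
        p = p * batch
        p = p / p.sum()
        lam = p * d
        od = phi > 1e-12
        if od.any():
            lam = lam.copy()
            lam[od] = rng.gamma(1.0 / phi[od], p[od] * d * phi[od])
        counts[:, j] = rng.poisson(lam)
    cdf = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                       columns=list(design["sample_id"]))
    return CountMatrix(counts=cdf, design=design.reset_index(drop=True))


def expected_proportions(truth: SimulationTruth, compound: str,
                         generations: float,
                         initial_freq: np.ndarray | None = None) -> pd.Series:
    """Closed-form expected read proportions for a treatment sample."""
    n = truth.s.shape[0]
    f0 = np.full(n, 1.0 / n) if initial_freq is None else initial_freq
    p = f0 * np.exp2(generations * truth.s[compound].to_numpy())
    return pd.Series(p / p.sum(), index=truth.s.index)


# ---------------------------------------------------------------------------
# FASTQ emission


def emit_fastq(counts: CountMatrix, catalog: pd.DataFrame, outdir,
               error_rate: float = 0.0, seed: int = 0) -> dict[str, Path]:
    """Write one FASTQ file per sample; reads are the strain up-tags.

    Each strain contributes exactly its count-matrix entry in reads; per-base
    substitution errors are applied at ``error_rate``. Reads start with the
    barcode (offset 0) and have constant length equal to the barcode length.
    """
    if not (0.0 <= error_rate < 0.25):
        raise ValueError("error_rate must be in [0, 0.25)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cat = catalog.set_index("gene").loc[counts.counts.index]
    codes = np.array([[("ACGT".index(b)) for b in bc] for bc in cat["uptag"]],
                     dtype=np.uint8)
    L = codes.shape[1]
    qual = "I" * L
    paths: dict[str, Path] = {}
    for sample in counts.counts.columns:
        col = counts.counts[sample].to_numpy()
        reads = np.repeat(codes, col, axis=0)
        if error_rate > 0 and reads.size:
            mask = rng.random(reads.shape) < error_rate
            shift = rng.integers(1, 4, mask.sum(), dtype=np.uint8)
            reads[mask] = (reads[mask] + shift) % 4
        if reads.size:
            reads = reads[rng.permutation(reads.shape[0])]
        seqs = BASES[reads]
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for i in range(seqs.shape[0]):
                fh.write(f"@{sample}.{i}\n{seqs[i].tobytes().decode()}\n+\n{qual}\n")
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# Gene sets and reference compendium


def generate_genesets(catalog: pd.DataFrame, n_sets: int,
                      size_range: tuple[int, int] = (5, 50), seed: int = 0,
                      truth: SimulationTruth | None = None,
                      planted: list[tuple[str, str, int]] = ()
                      ) -> "OrderedDict[str, list[str]]":
    """Random gene sets, plus optional sets planted within a gene class.

    ``planted`` entries are ``(set_name, gene_class, size)``; their members
    are drawn from genes of that class in ``truth`` so that enrichment
    recovery is testable end to end.
    """
    lo, hi = size_range
    genes = list(catalog["gene"])
    if hi > len(genes):
        raise ValueError("size_range exceeds number of genes")
    if lo < 1 or lo > hi:
        raise ValueError("invalid size_range")
    rng = np.random.default_rng(seed)
    sets: OrderedDict[str, list[str]] = OrderedDict()
    for name, cls, size in planted:
        if truth is None:
            raise ValueError("planted sets require truth")
        pool = list(truth.gene_class.index[truth.gene_class == cls])
        if size > len(pool):
            raise ValueError(f"planted set {name}: only {len(pool)} genes of "
                             f"class {cls}")
        sets[name] = sorted(rng.choice(pool, size, replace=False))
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"set_{i:03d}"] = sorted(rng.choice(genes, size, replace=False))
    return sets


def generate_compendium(catalog: pd.DataFrame, n_ref_compounds: int = 30,
                        n_signature_sets: int = 5, seed: int = 0,
                        n_diagnostic: int = 40, z_diag: float = 5.0,
                        noise_sd: float = 1.0) -> ReferenceCompendium:
    """Reference compound x gene z-score matrix with planted diagnostic genes.

    Each planted gene carries sign-consistent |z| = ``z_diag`` scores in every
    compound of one signature set and background noise elsewhere; compounds
    are partitioned evenly into the signature sets.
    """
    if n_signature_sets > n_ref_compounds:
        raise ValueError("more signature sets than reference compounds")
    if n_signature_sets < 1:
        raise ValueError("need >= 1 signature set")
    rng = np.random.default_rng(seed)
    genes = list(catalog["gene"])
    comps = [f"ref_{i:03d}" for i in range(n_ref_compounds)]
    set_names = [f"sig_{chr(ord('A') + i)}" for i in range(n_signature_sets)]
    set_map = pd.Series([set_names[i % n_signature_sets]
                         for i in range(n_ref_compounds)],
                        index=comps, name="signature_set")
    z = rng.normal(0.0, noise_sd, (n_ref_compounds, len(genes)))
    n_diag = min(n_diagnostic, len(genes))
    diag_genes = rng.choice(len(genes), n_diag, replace=False)
    rows = []
    for gi in diag_genes:
        sname = set_names[int(rng.integers(0, n_signature_sets))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        members = np.flatnonzero(set_map.to_numpy() == sname)
        z[members, gi] = sign * (z_diag + rng.normal(0.0, 0.2, members.size))
        rows.append({"gene": genes[gi], "signature_set": sname,
                     "sign": "positive" if sign > 0 else "negative"})
    zdf = pd.DataFrame(z, index=pd.Index(comps, name="compound"), columns=genes)
    return ReferenceCompendium(z=zdf, set_map=set_map,
                               planted=pd.DataFrame(rows))
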