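"""Seeded generator of a complete synthetic study: expression, annotation,
tissue panel, ChIP peaks, 3'UTR sequences, gene sets, and a ground-truth
manifest against which the downstream analysis stages can be scored.

Design: expression is multivariate normal on the log2 scale (FPKM =
2^log-expression), with planted sparse-precision modules linking lncRNAs and
mRNAs, per-condition mean shifts for planted differential programs, and
independent residual noise.  One global seed feeds a fixed set of named
sub-streams, so regenerating one component never perturbs the draws of
another.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneRecord,
    GeneSetCollection,
    PeakSet,
    write_annotation,
    write_bed,
    write_expression,
    write_fasta,
    write_gmt,
)
from .motif_scan import max_packed_count

# The five contrasts: (name, depot, treatment condition, browning sign).
# +1 = browning / BAT activation (induction is concordant-up); -1 = whitening.
CONTRASTS = (
    ("iWAT_cold", "iWAT", "cold", 1),
    ("iWAT_cl316243", "iWAT", "cl316243", 1),
    ("iWAT_exercise", "iWAT", "exercise", 1),
    ("BAT_acute_cold", "BAT", "acute_cold", 1),
    ("BAT_thermoneutral", "BAT", "thermoneutral", -1),
)

CONDITION_GROUPS = (
    ("iWAT", "control"),
    ("iWAT", "cold"),
    ("iWAT", "cl316243"),
    ("iWAT", "exercise"),
    ("BAT", "control"),
    ("BAT", "acute_cold"),
    ("BAT", "thermoneutral"),
)

SIGN_CONVENTIONS = {name: sign for name, _, _, sign in CONTRASTS}

# fixed sub-stream indices for the counter-based seed split
_STREAMS = {
    "truth": 0,
    "expression": 1,
    "annotation": 2,
    "peaks_pparg": 3,
    "peaks_prdm16": 4,
    "utrs": 5,
    "tissue": 6,
    "gene_sets": 7,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[component],))
    )


@dataclass(frozen=True)
class ModuleSpec:
    name: str
    n_mrna: int = 3
    n_lnc: int = 1
    topology: str = "clique"     # clique | band | random
    strength: float = 0.3        # magnitude of precision off-diagonals
    program: str = "up"          # browning-up or browning-down program
    lnc_hub_degree: int = 0      # extra mRNA partners wired to each lncRNA
    lnc_hub_strength: float = 0.25

    @property
    def size(self) -> int:
        return self.n_mrna + self.n_lnc


# Small near-clique modules: the positive-definiteness budget of a precision
# matrix caps the sum of a node's partial correlations near 1, so recoverable
# edge strengths (|pcor| ~ 0.3) require low degree; 4-cliques are the densest
# option and form natural modularity communities.
_UP_MODULE_NAMES = (
    "thermogenesis", "lipid_metabolism", "oxidative_phosphorylation",
    "fatty_acid_oxidation", "mitochondrial_biogenesis",
    "respiratory_electron_transport", "tca_cycle", "glucose_uptake",
    "adipocyte_differentiation", "camp_signaling",
)
_DOWN_MODULE_NAMES = (
    "immune_response", "inflammation", "rna_processing", "translation",
    "wat_identity", "cell_adhesion", "extracellular_matrix",
    "complement_cascade", "chemotaxis", "apoptosis",
)


def default_modules() -> list[ModuleSpec]:
    specs = [ModuleSpec(name=n, program="up") for n in _UP_MODULE_NAMES]
    specs += [ModuleSpec(name=n, program="down") for n in _DOWN_MODULE_NAMES]
    return specs


@dataclass
class SimConfig:
    seed: int
    n_mrna: int = 2000
    n_lnc: int = 150
    replicates: int = 3
    modules: list[ModuleSpec] = field(default_factory=default_modules)
    de_frac_up: float = 0.08
    de_frac_down: float = 0.08
    effect_size: float = 6.5          # log2 units
    sharing: float = 0.5              # fraction of each program from the core
    noise_sd: float = 0.3             # residual sd for non-module genes
    module_var: float = 0.4           # per-gene variance of the module latent
    baseline_lo: float = 1.5          # baseline log2 mean range
    baseline_hi: float = 9.0
    depot_shift_frac: float = 0.2     # genes carrying a depot signature
    depot_shift_size: float = 2.0
    n_tissues: int = 29
    peak_rate: float = 0.9
    background_peaks: int = 300
    peak_width: int = 400
    promoter_window: int = 50_000
    contig_length: int = 50_000_000
    utr_len: int = 400
    scan_window: int = 100
    cbs_counts: tuple = (20, 21, 22, 24, 26, 28, 30, 35)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, val in (
            ("de_frac_up", self.de_frac_up), ("de_frac_down", self.de_frac_down),
            ("sharing", self.sharing), ("peak_rate", self.peak_rate),
            ("depot_shift_frac", self.depot_shift_frac),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {val}")
        tot_mrna = sum(m.n_mrna for m in self.modules)
        tot_lnc = sum(m.n_lnc for m in self.modules)
        if tot_mrna > self.n_mrna or tot_lnc > self.n_lnc:
            raise ValueError("module sizes exceed the gene universe")
        bound = max_packed_count(self.scan_window)
        for c in self.cbs_counts:
            if c > bound:
                raise ValueError(
                    f"planned UGU count {c} infeasible in a {self.scan_window}"
                    f"-nt window (max {bound})"
                )
        if self.n_tissues < 4:
            raise ValueError("tissue panel needs >= 4 tissues")


@dataclass
class SyntheticTruth:
    """Ground-truth manifest of everything the generator planted."""

    config: SimConfig
    gene_ids: list[str]
    biotypes: dict[str, str]
    modules: dict[str, list[str]]
    true_edges: list[tuple[str, str]]
    directions: dict[str, dict[str, int]]       # contrast -> gene -> +-1
    core_up: list[str]
    core_down: list[str]
    peak_targets: list[str]
    cbs_windows: dict[str, dict]                # gene -> {start, count}
    tissue_sets: dict[str, list[str]]
    thermogenic_lnc: str
    annotation: dict[str, GeneRecord]
    baseline_log2: np.ndarray
    depot_offset: dict[str, np.ndarray]
    cholesky: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def planted_in_at_least(self, k: int, direction: int = 1) -> set:
        """Genes planted with the given browning-sense direction in >= k
        contrasts (whitening counts via its flipped observed sign)."""
        counts: dict[str, int] = {}
        for name, _, _, sign in CONTRASTS:
            for gene, d in self.directions[name].items():
                if d * sign == direction:
                    counts[gene] = counts.get(gene, 0) + 1
        return {g for g, c in counts.items() if c >= k}

    def module_assignment(self) -> dict[str, int]:
        return {
            g: i for i, (_, genes) in enumerate(sorted(self.modules.items()))
            for g in genes
        }

    def to_json(self) -> str:
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
                if k != "modules"
            },
            "module_specs": [asdict(m) for m in self.config.modules],
            "gene_ids": self.gene_ids,
            "biotypes": self.biotypes,
            "modules": self.modules,
            "true_edges": [list(e) for e in self.true_edges],
            "directions": self.directions,
            "core_up": self.core_up,
            "core_down": self.core_down,
            "peak_targets": self.peak_targets,
            "cbs_windows": self.cbs_windows,
            "tissue_sets": self.tissue_sets,
            "thermogenic_lnc": self.thermogenic_lnc,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Precision-matrix construction
# ---------------------------------------------------------------------------

def _module_precision(spec: ModuleSpec, member_biotypes: list[str],
                      rng: np.random.Generator) -> np.ndarray:
    """Symmetric positive-definite precision with the requested topology.

    Band: tridiagonal chain.  Random: Erdos-Renyi support at ~2 partners per
    node.  Every lncRNA additionally gets ``lnc_hub_degree`` mRNA partners so
    that neighborhood extraction has recoverable structure.  Positive
    definiteness is enforced by scaling off-diagonals until the smallest
    eigenvalue clears a margin.
    """
    p = len(member_biotypes)
    k = np.zeros((p, p))
    s = spec.strength
    if spec.topology == "clique":
        k[:] = -s
    elif spec.topology == "band":
        for i in range(p - 1):
            k[i, i + 1] = k[i + 1, i] = -s
    elif spec.topology == "random":
        prob = min(1.0, 2.0 / max(p - 1, 1))
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < prob:
                    k[i, j] = k[j, i] = -s
    else:
        raise ValueError(f"unknown topology {spec.topology!r}")
    mrna_idx = [i for i, b in enumerate(member_biotypes) if b == "mRNA"]
    for i, b in enumerate(member_biotypes):
        if b != "lncRNA" or not mrna_idx:
            continue
        partners = rng.choice(
            mrna_idx, size=min(spec.lnc_hub_degree, len(mrna_idx)),
            replace=False,
        )
        for j in partners:
            if k[i, j] == 0:
                k[i, j] = k[j, i] = -spec.lnc_hub_strength
    np.fill_diagonal(k, 1.0)
    for _ in range(100):
        if np.linalg.eigvalsh(k).min() > 0.05:
            break
        off = k - np.diag(np.diag(k))
        k = np.diag(np.diag(k)) + 0.9 * off
    else:
        raise ValueError(
            f"module {spec.name!r}: requested structure is not positive "
            "definite"
        )
    return k


def _scaled_covariance(precision: np.ndarray, target_var: float) -> np.ndarray:
    """Invert and rescale to a correlation-shaped covariance with the given
    per-gene variance (partial-correlation structure is scale-invariant)."""
    cov = np.linalg.inv(precision)
    d = np.sqrt(np.diag(cov))
    return target_var * cov / np.outer(d, d)


# ---------------------------------------------------------------------------
# Truth construction
# ---------------------------------------------------------------------------

def build_truth(config: SimConfig) -> SyntheticTruth:
    config.validate()
    rng = _rng(config.seed, "truth")

    wm = len(str(config.n_mrna))
    wl = len(str(config.n_lnc))
    mrna_ids = [f"m{i + 1:0{wm}d}" for i in range(config.n_mrna)]
    lnc_ids = [f"l{i + 1:0{wl}d}" for i in range(config.n_lnc)]
    gene_ids = mrna_ids + lnc_ids
    biotypes = {g: "mRNA" for g in mrna_ids}
    biotypes.update({g: "lncRNA" for g in lnc_ids})

    # --- module membership: sequential from the head of each id list, with
    # lncRNAs interleaved so band neighbors of a lncRNA are mRNAs
    modules: dict[str, list[str]] = {}
    cholesky: dict[str, np.ndarray] = {}
    true_edges: list[tuple[str, str]] = []
    mi, li = 0, 0
    for spec in config.modules:
        mr = mrna_ids[mi:mi + spec.n_mrna]
        ln = lnc_ids[li:li + spec.n_lnc]
        mi += spec.n_mrna
        li += spec.n_lnc
        members: list[str] = []
        if spec.n_lnc:
            stride = max(1, spec.size // (spec.n_lnc + 1))
            lq = list(ln)
            mq = list(mr)
            for pos in range(spec.size):
                if lq and (pos + 1) % (stride + 1) == 0:
                    members.append(lq.pop(0))
                else:
                    members.append(mq.pop(0) if mq else lq.pop(0))
            members.extend(lq)
        else:
            members = list(mr)
        precision = _module_precision(
            spec, [biotypes[g] for g in members], rng
        )
        cov = _scaled_covariance(precision, config.module_var)
        cholesky[spec.name] = np.linalg.cholesky(cov)
        modules[spec.name] = members
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if precision[i, j] != 0:
                    a, b = sorted((members[i], members[j]))
                    true_edges.append((a, b))

    up_module_genes = [
        g for spec in config.modules if spec.program == "up"
        for g in modules[spec.name]
    ]
    down_module_genes = [
        g for spec in config.modules if spec.program == "down"
        for g in modules[spec.name]
    ]

    # --- differential programs: a shared core (containing all module genes of
    # the matching program) plus disjoint per-contrast specific genes
    def _core(target_mrna: int, target_lnc: int, module_genes: list[str],
              mrna_pool: list[str], lnc_pool: list[str]) -> list[str]:
        core = list(module_genes)
        have_m = sum(1 for g in core if biotypes[g] == "mRNA")
        have_l = len(core) - have_m
        core += mrna_pool[: max(0, target_mrna - have_m)]
        core += lnc_pool[: max(0, target_lnc - have_l)]
        return core

    free_mrna = mrna_ids[mi:]
    free_lnc = lnc_ids[li:]
    n_up_m = round(config.sharing * config.de_frac_up * config.n_mrna)
    n_up_l = round(config.sharing * config.de_frac_up * config.n_lnc)
    n_dn_m = round(config.sharing * config.de_frac_down * config.n_mrna)
    n_dn_l = round(config.sharing * config.de_frac_down * config.n_lnc)
    core_up = _core(n_up_m, n_up_l, up_module_genes, free_mrna, free_lnc)
    used_m = sum(1 for g in core_up if biotypes[g] == "mRNA" and g in free_mrna)
    used_l = sum(1 for g in core_up if biotypes[g] == "lncRNA" and g in free_lnc)
    free_mrna = free_mrna[used_m:]
    free_lnc = free_lnc[used_l:]
    core_down = _core(n_dn_m, n_dn_l, down_module_genes, free_mrna, free_lnc)
    used_m = sum(1 for g in core_down if biotypes[g] == "mRNA" and g in free_mrna)
    used_l = sum(1 for g in core_down if biotypes[g] == "lncRNA" and g in free_lnc)
    free_pool = free_mrna[used_m:] + free_lnc[used_l:]

    prog_up = round(config.de_frac_up * config.n_mrna) + round(
        config.de_frac_up * config.n_lnc
    )
    prog_dn = round(config.de_frac_down * config.n_mrna) + round(
        config.de_frac_down * config.n_lnc
    )
    n_spec_up = max(0, prog_up - len(core_up))
    n_spec_dn = max(0, prog_dn - len(core_down))
    need = 5 * (n_spec_up + n_spec_dn)
    if need > len(free_pool):
        raise ValueError(
            f"not enough unassigned genes ({len(free_pool)}) for "
            f"{need} contrast-specific program slots"
        )
    shuffled = list(free_pool)
    rng.shuffle(shuffled)
    cursor = 0
    directions: dict[str, dict[str, int]] = {}
    for name, _depot, _cond, sign in CONTRASTS:
        spec_up = shuffled[cursor:cursor + n_spec_up]
        cursor += n_spec_up
        spec_dn = shuffled[cursor:cursor + n_spec_dn]
        cursor += n_spec_dn
        d: dict[str, int] = {}
        for g in list(core_up) + spec_up:
            d[g] = sign          # browning-up program
        for g in list(core_down) + spec_dn:
            d[g] = -sign
        directions[name] = d

    # --- annotation: one synthetic contig per depot, genes alternating
    arng = _rng(config.seed, "annotation")
    annotation: dict[str, GeneRecord] = {}
    contigs = ("chr1", "chr2")
    per_contig = [gene_ids[0::2], gene_ids[1::2]]
    for contig, genes in zip(contigs, per_contig):
        spacing = config.contig_length // (len(genes) + 1)
        for i, g in enumerate(genes):
            tss = (i + 1) * spacing + int(arng.integers(-2000, 2001))
            tss = max(0, min(config.contig_length - 1, tss))
            strand = "+" if arng.random() < 0.5 else "-"
            utr_start = min(tss + 2000, config.contig_length - config.utr_len)
            annotation[g] = GeneRecord(
                gene_id=g, biotype=biotypes[g], chrom=contig, strand=strand,
                tss=tss, utr3=(utr_start, utr_start + config.utr_len),
            )
    annotation = {g: annotation[g] for g in gene_ids}

    # --- baselines and depot signature (shared across replicate settings)
    baseline = rng.uniform(config.baseline_lo, config.baseline_hi,
                           size=len(gene_ids))
    n_shift = round(config.depot_shift_frac * len(gene_ids))
    shift_idx = rng.choice(len(gene_ids), size=n_shift, replace=False)
    shift = np.zeros(len(gene_ids))
    shift[shift_idx] = rng.uniform(
        -config.depot_shift_size, config.depot_shift_size, size=n_shift
    )
    depot_offset = {"iWAT": np.zeros(len(gene_ids)), "BAT": shift}

    # --- regulatory truth
    peak_targets = sorted(core_up)
    thermo_lncs = [
        g for g in modules.get("thermogenesis", []) if biotypes[g] == "lncRNA"
    ]
    thermogenic_lnc = thermo_lncs[0] if thermo_lncs else ""
    core_up_mrna = [g for g in core_up if biotypes[g] == "mRNA"]
    immune = [
        g for g in modules.get("immune_response", [])
        if biotypes[g] == "mRNA"
    ]
    tissue_sets = {"BAT": sorted(core_up_mrna)}
    if immune:
        tissue_sets["spleen"] = sorted(immune)

    cbs_genes = core_up_mrna[: len(config.cbs_counts)]
    cbs_windows = {
        g: {"start": 150, "count": int(c)}
        for g, c in zip(cbs_genes, config.cbs_counts)
    }

    return SyntheticTruth(
        config=config,
        gene_ids=gene_ids,
        biotypes=biotypes,
        modules={k: list(v) for k, v in modules.items()},
        true_edges=sorted(set(true_edges)),
        directions=directions,
        core_up=sorted(core_up),
        core_down=sorted(core_down),
        peak_targets=peak_targets,
        cbs_windows=cbs_windows,
        tissue_sets=tissue_sets,
        thermogenic_lnc=thermogenic_lnc,
        annotation=annotation,
        baseline_log2=baseline,
        depot_offset=depot_offset,
        cholesky=cholesky,
    )


# ---------------------------------------------------------------------------
# Component simulators
# ---------------------------------------------------------------------------

def simulate_expression(truth: SyntheticTruth, config: SimConfig | None = None,
                        replicates: int | None = None) -> ExpressionMatrix:
    """Draw the FPKM matrix: per sample, log2 expression = baseline + depot
    signature + condition effect + module latent (module genes) or
    independent residual noise (all other genes).

    Module genes draw only the module latent, so the data-generating
    covariance of a module is exactly the planted (scaled) inverse precision
    and the planted partial-correlation structure is exact.
    """
    config = config or truth.config
    replicates = replicates or config.replicates
    rng = _rng(config.seed, "expression")
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    n_genes = len(truth.gene_ids)
    in_module = np.zeros(n_genes, dtype=bool)
    for genes in truth.modules.values():
        for g in genes:
            in_module[gene_index[g]] = True

    contrast_by_group = {
        (depot, cond): name for name, depot, cond, _ in CONTRASTS
    }
    module_members = {
        name: [gene_index[g] for g in genes]
        for name, genes in truth.modules.items()
    }

    sample_ids, meta_rows, columns = [], [], []
    for depot, condition in CONDITION_GROUPS:
        for r in range(1, replicates + 1):
            sid = f"{depot}_{condition}_r{r}"
            mean = truth.baseline_log2 + truth.depot_offset[depot]
            cname = contrast_by_group.get((depot, condition))
            effect = np.zeros(n_genes)
            if cname is not None:
                for g, d in truth.directions[cname].items():
                    effect[gene_index[g]] = d * config.effect_size
            x = mean + effect
            for name, idx in module_members.items():
                z = truth.cholesky[name] @ rng.standard_normal(len(idx))
                x[idx] += z
            noise = rng.normal(0.0, config.noise_sd, size=n_genes)
            x[~in_module] += noise[~in_module]
            sample_ids.append(sid)
            meta_rows.append(
                {"depot": depot, "condition": condition, "replicate": r}
            )
            columns.append(np.exp2(x))
    values = pd.DataFrame(
        np.column_stack(columns), index=truth.gene_ids, columns=sample_ids
    )
    meta = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionMatrix(values, meta)


def simulate_peaks(truth: SyntheticTruth, source: str,
                   config: SimConfig | None = None) -> PeakSet:
    """Plant >= 1 peak inside each target gene's strand-aware upstream window
    (at the configured rate) plus uniform background peaks."""
    config = config or truth.config
    stream = f"peaks_{source}"
    if stream not in _STREAMS:
        raise ValueError(f"unknown peak source {source!r}")
    rng = _rng(config.seed, stream)
    width = config.peak_width
    records = []
    for g in truth.peak_targets:
        if rng.random() >= config.peak_rate:
            continue
        rec = truth.annotation[g]
        if rec.strand == "+":
            lo, hi = rec.tss - config.promoter_window, rec.tss
        else:
            lo, hi = rec.tss, rec.tss + config.promoter_window
        if lo < 0:
            warnings.warn(
                f"upstream window of {g} clipped at contig start"
            )
            lo = 0
        hi = min(hi, config.contig_length)
        start = int(rng.integers(lo, max(lo + 1, hi - width)))
        records.append((rec.chrom, start, min(start + width, hi), 1.0))
    chroms = sorted({r.chrom for r in truth.annotation.values()})
    for _ in range(config.background_peaks):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, config.contig_length - width))
        records.append((chrom, start, start + width, None))
    return PeakSet(source=source, records=records)


_BACKGROUND_ALPHABET = np.array(list("ACGU"))


def simulate_utrs(truth: SyntheticTruth,
                  config: SimConfig | None = None) -> dict[str, str]:
    """Random-composition 3'UTRs with one exact-count UGU window planted per
    CBS-planned gene.

    The planted window holds an overlapping "UGUGU..." run (a run of length
    2c+1 has exactly c occurrences) padded with non-matching bases, and the
    100 nt on each side of the window are U-free, so the gene's maximal
    window count equals the planned count exactly.
    """
    config = config or truth.config
    rng = _rng(config.seed, "utrs")
    win = config.scan_window
    seqs: dict[str, str] = {}
    for g in truth.gene_ids:
        rec = truth.annotation[g]
        length = rec.utr3[1] - rec.utr3[0]
        seq = list(rng.choice(_BACKGROUND_ALPHABET, size=length))
        plan = truth.cbs_windows.get(g)
        if plan is not None:
            c = plan["count"]
            start = plan["start"]
            if start + win > length:
                raise ValueError(
                    f"planted window for {g} exceeds its UTR length"
                )
            run = "UG" * c + "U"
            pad = win - len(run)
            window = run + "A" + "C" * (pad - 1) if pad else run
            guard_lo = max(0, start - win)
            guard_hi = min(length, start + win + win)
            for i in range(guard_lo, guard_hi):
                if seq[i] == "U":
                    seq[i] = "C"
            seq[start:start + win] = list(window)
        seqs[g] = "".join(seq)
    return seqs


def simulate_tissue_panel(truth: SyntheticTruth,
                          config: SimConfig | None = None) -> pd.DataFrame:
    """Genes x tissues FPKM panel with planted tissue-enriched sets."""
    config = config or truth.config
    rng = _rng(config.seed, "tissue")
    named = ["BAT", "iWAT", "eWAT", "spleen"]
    generic = [f"tissue_{i:02d}" for i in range(5, config.n_tissues + 1)]
    tissues = named + generic
    n_genes = len(truth.gene_ids)
    base = np.exp2(rng.uniform(0.0, 6.0, size=n_genes))
    noise = np.exp2(rng.normal(0.0, 0.5, size=(n_genes, len(tissues))))
    panel = pd.DataFrame(
        base[:, None] * noise, index=truth.gene_ids, columns=tissues
    )
    for tissue, genes in truth.tissue_sets.items():
        if tissue not in panel.columns:
            continue
        rows = [g for g in genes if g in panel.index]
        enriched = np.exp2(rng.uniform(4.5, 6.5, size=len(rows)))
        low = np.exp2(rng.normal(-1.0, 0.5, size=(len(rows), len(tissues))))
        panel.loc[rows, :] = low
        panel.loc[rows, tissue] = enriched
    return panel


def simulate_gene_sets(truth: SyntheticTruth,
                       config: SimConfig | None = None,
                       n_decoys: int = 10,
                       decoy_size: int = 40) -> GeneSetCollection:
    """Module-derived functional sets plus random decoy sets (mRNAs only)."""
    config = config or truth.config
    rng = _rng(config.seed, "gene_sets")
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    for name, genes in truth.modules.items():
        members = tuple(g for g in genes if truth.biotypes[g] == "mRNA")
        if members:
            sets[name] = members
            descriptions[name] = f"planted module {name}"
    mrnas = [g for g in truth.gene_ids if truth.biotypes[g] == "mRNA"]
    for i in range(n_decoys):
        members = rng.choice(mrnas, size=min(decoy_size, len(mrnas)),
                             replace=False)
        name = f"decoy_{i + 1:02d}"
        sets[name] = tuple(sorted(members))
        descriptions[name] = "random decoy set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# Full-study emission
# ---------------------------------------------------------------------------

def generate_study(config: SimConfig) -> dict:
    """Build truth and every derived component in memory."""
    truth = build_truth(config)
    return {
        "truth": truth,
        "expression": simulate_expression(truth, config),
        "peaks": {
            src: simulate_peaks(truth, src, config)
            for src in ("pparg", "prdm16")
        },
        "utrs": simulate_utrs(truth, config),
        "tissue_panel": simulate_tissue_panel(truth, config),
        "gene_sets": simulate_gene_sets(truth, config),
    }


def write_study(study: dict, outdir) -> dict[str, Path]:
    """Write all generator outputs under ``outdir``; deterministic bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth: SyntheticTruth = study["truth"]
    paths = {
        "expression": outdir / "expression.tsv",
        "meta": outdir / "meta.tsv",
        "annotation": outdir / "annotation.tsv",
        "utrs": outdir / "utrs.fasta",
        "tissue_panel": outdir / "tissue_panel.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.json",
    }
    write_expression(study["expression"], paths["expression"], paths["meta"])
    write_annotation(truth.annotation, paths["annotation"])
    for src, peaks in study["peaks"].items():
        paths[f"peaks_{src}"] = outdir / f"peaks_{src}.bed"
        write_bed(peaks, paths[f"peaks_{src}"])
    write_fasta(study["utrs"], paths["utrs"])
    study["tissue_panel"].to_csv(paths["tissue_panel"], sep="\t",
                                 index_label="gene_id")
    write_gmt(study["gene_sets"], paths["gene_sets"])
    paths["truth"].write_text(truth.to_json())
    return paths


def null_config(seed: int, n_mrna: int = 300, n_lnc: int = 30,
                replicates: int = 3) -> SimConfig:
    """No planted DE, no modules: the calibration null."""
    return SimConfig(
        seed=seed, n_mrna=n_mrna, n_lnc=n_lnc, replicates=replicates,
        modules=[], de_frac_up=0.0, de_frac_down=0.0, sharing=0.0,
        cbs_counts=(),
    )
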