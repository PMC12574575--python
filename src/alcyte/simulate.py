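"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the statistical design the analysis assumes: a blood
cohort with six immune cell types mixed per sample by Dirichlet proportions;
cell-type-specific beta-distributed methylomes and log-normal transcriptomes;
bulk signals as proportion-weighted mixtures plus noise; a 14-marker biomarker
panel whose dichotomized sum defines high/low allostatic-load groups; chrX
probes carrying an X-inactivation-like intermediate methylation signal in
females; and planted CpG-gene pairs — a beta shift in a subset of high-AL
samples of one cell type, coupled to an expression shift whose sign makes the
pair detectable in the intended correlation mode.

Everything is keyed in a :class:`TruthTable` so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

CELL_TYPES = ["CD8T", "CD4T", "B", "NK", "Neutrophils", "Monocytes"]
DEFAULT_ALPHA = (10.0, 8.0, 3.0, 2.0, 14.0, 5.0)
STRATA = ["typeII", "typeI_red", "typeI_green"]


@dataclass(frozen=True)
class PlantedPair:
    """One planted functional CpG-gene pair."""

    cell_type: str
    mode: str  # 'negative' | 'positive'
    state: str  # 'hypo' | 'hyper' | 'dual'
    effect_size: float = 0.3  # beta units
    expr_shift: float = 2.0  # in SD units of log expression
    subset_frac: float = 0.3  # fraction of high-AL samples affected


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: 429 samples of which 126 high-AL, six
    blood cell types with a Dirichlet mixing skewed toward neutrophils, and a
    desk-scale feature space (2,000 CpGs × 1,500 genes) so the full pipeline
    runs in minutes.
    """

    n_samples: int = 429
    n_cpgs: int = 2000
    n_genes: int = 1500
    n_celltypes: int = 6
    dirichlet_alpha: tuple = DEFAULT_ALPHA
    n_high: int = 126
    planted_pairs: tuple = ()
    meth_noise_sd: float = 0.03
    expr_noise_sd: float = 0.1  # multiplicative, on log scale
    expr_profile_sd: float = 0.2  # per-sample cell-level log-scale spread
    biomarker_noise_sd: float = 1.0
    n_signature_genes: int = 300
    frac_discriminative: float = 0.2
    n_chrx_probes: int = 60
    n_blacklist: int = 20
    unmapped_gene_frac: float = 0.02
    n_sex_mismatches: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.n_high < self.n_samples:
            raise ValueError("n_high must lie strictly between 0 and n_samples")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if len(self.dirichlet_alpha) != self.n_celltypes:
            raise ValueError("dirichlet_alpha length must equal n_celltypes")
        for p in self.planted_pairs:
            if not 0 < p.subset_frac < 1:
                raise ValueError("planted subset_frac must lie in (0,1)")
            if p.effect_size <= 0 or p.expr_shift <= 0:
                raise ValueError("planted effect sizes must be > 0")
            if p.cell_type not in CELL_TYPES[: self.n_celltypes]:
                raise ValueError(f"unknown planted cell type {p.cell_type!r}")
            if p.mode not in ("negative", "positive") or p.state not in (
                "hypo", "hyper", "dual",
            ):
                raise ValueError("planted mode/state invalid")


def default_planted_pairs(n: int = 20, effect_size: float = 0.3,
                          expr_shift: float = 2.0, subset_frac: float = 0.3) -> tuple:
    """A balanced default pair table across abundant cell types/modes/states."""
    cts = ["Neutrophils", "CD8T", "CD4T", "Monocytes"]
    combos = [
        (m, s) for m in ("negative", "positive") for s in ("hyper", "hypo", "dual")
    ]
    pairs = []
    for i in range(n):
        mode, state = combos[i % len(combos)]
        pairs.append(PlantedPair(
            cell_type=cts[i % len(cts)], mode=mode, state=state,
            effect_size=effect_size, expr_shift=expr_shift, subset_frac=subset_frac,
        ))
    return tuple(pairs)


@dataclass
class Reference:
    """Cell-type-level methylation/expression profiles and feature metadata."""

    meth_profiles: pd.DataFrame  # (CpG, cell type) multi-col: cell types as columns
    expr_profiles: pd.DataFrame  # gene symbol × cell type
    cpg_ids: list
    gene_symbols: list
    source_ids: list  # pre-mapping expression row ids
    signature_genes: list
    discriminative_cpgs: list
    chrx_ids: list
    chrx_female: np.ndarray
    chrx_male: np.ndarray


@dataclass
class TruthTable:
    """Planted ground truth, keyed for recovery tests."""

    proportions: pd.DataFrame  # sample × cell type
    planted: pd.DataFrame  # one row per planted pair with coordinates & direction
    affected_samples: dict  # pair idx → {'hypo': [...], 'hyper': [...]}
    sexes: pd.Series
    mismatched_samples: list
    al_scores: pd.Series
    al_groups: pd.Series
    reference: Reference = None


@dataclass
class Cohort:
    """The full synthetic input bundle plus its truth table."""

    beta: pd.DataFrame  # CpG × sample (includes chrX probes)
    expression: pd.DataFrame  # source id × sample
    panel: pd.DataFrame  # sample × (biomarkers + covariates)
    thresholds: pd.DataFrame
    annotation: pd.DataFrame  # cpg → chrom, stratum, gene, blacklist
    gene_map: pd.Series  # source id → symbol (NaN = unmapped)
    signature: pd.DataFrame  # gene symbol × cell type
    truth: TruthTable


def _direction_of(state: str, mode: str) -> str:
    up = (state == "hypo" and mode == "negative") or (state == "hyper" and mode == "positive")
    return "up" if up else "down"


def generate_reference(config: SimConfig, rng: np.random.Generator | None = None) -> Reference:
    """Draw cell-type-level methylation and expression profiles.

    CpG means come from a mixture of low Beta(2,10), mid Beta(5,5) and high
    Beta(10,2) regimes shared across cell types; a configurable fraction of
    CpGs is made cell-type-discriminative (one cell type high, the others
    low). Signature genes get a distinct marker cell type with elevated
    expression; chrX probes get sex-dependent regimes for the sex-inference
    stage.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    H = config.n_celltypes
    cts = CELL_TYPES[:H]
    cpg_ids = [f"cg{i:06d}" for i in range(config.n_cpgs)]
    gene_symbols = [f"GENE{i:05d}" for i in range(config.n_genes)]
    source_ids = [f"ENSG{i:08d}" for i in range(config.n_genes)]

    regime = rng.integers(0, 3, size=config.n_cpgs)
    base = np.where(
        regime == 0, rng.beta(2, 10, config.n_cpgs),
        np.where(regime == 1, rng.beta(5, 5, config.n_cpgs), rng.beta(10, 2, config.n_cpgs)),
    )
    meth = np.tile(base[:, None], (1, H))
    n_disc = int(config.frac_discriminative * config.n_cpgs)
    disc_idx = rng.choice(config.n_cpgs, size=n_disc, replace=False)
    hot = rng.integers(0, H, size=n_disc)
    for j, h in zip(disc_idx, hot):
        meth[j, :] = rng.uniform(0.1, 0.3, H)
        meth[j, h] = rng.uniform(0.7, 0.9)

    base_expr = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=config.n_genes)
    expr = np.tile(base_expr[:, None], (1, H))
    # signature genes are capped at half the gene pool so planted pairs and
    # ordinary genes always remain available
    n_sig = min(config.n_signature_genes, config.n_genes // 2)
    sig_genes = gene_symbols[:n_sig]
    for i in range(n_sig):
        marker_ct = i % H
        expr[i, :] = base_expr[i] * 0.5
        expr[i, marker_ct] = base_expr[i] * 5.0

    chrx_ids = [f"cgX{i:05d}" for i in range(config.n_chrx_probes)]
    chrx_female = np.clip(rng.normal(0.5, 0.04, config.n_chrx_probes), 0, 1)
    chrx_male = np.where(rng.random(config.n_chrx_probes) < 0.5,
                         rng.uniform(0.02, 0.12, config.n_chrx_probes),
                         rng.uniform(0.88, 0.98, config.n_chrx_probes))

    return Reference(
        meth_profiles=pd.DataFrame(meth, index=cpg_ids, columns=cts),
        expr_profiles=pd.DataFrame(expr, index=gene_symbols, columns=cts),
        cpg_ids=cpg_ids,
        gene_symbols=gene_symbols,
        source_ids=source_ids,
        signature_genes=sig_genes,
        discriminative_cpgs=[cpg_ids[j] for j in disc_idx],
        chrx_ids=chrx_ids,
        chrx_female=chrx_female,
        chrx_male=chrx_male,
    )


def _make_biomarkers(config: SimConfig, rng, samples, high_mask, sexes):
    """14-marker panel: high-AL samples get 3–6 markers pushed past threshold."""
    names = [f"marker_{i:02d}" for i in range(1, 14)] + ["hdl"]
    mus = rng.uniform(50, 150, 14)
    sds = rng.uniform(5, 15, 14)
    cutoffs = mus + sds  # risk above, except hdl: risk below mu - sd
    cutoffs[-1] = mus[-1] - sds[-1]
    n = len(samples)
    values = np.zeros((n, 14))
    k_true = np.zeros(n, dtype=int)
    for i in range(n):
        k = rng.integers(3, 7) if high_mask[i] else rng.integers(0, 3)
        k_true[i] = k
        risky = rng.choice(14, size=k, replace=False)
        for b in range(14):
            margin = np.abs(rng.normal(0.6, 0.25)) + 0.05
            side = 1.0 if b in risky else -1.0
            if b == 13:  # hdl: risk side is below
                side = -side
            values[i, b] = cutoffs[b] + side * margin * sds[b]
    panel = pd.DataFrame(values, index=samples, columns=names)
    panel["sex"] = sexes.to_numpy()
    panel["age"] = rng.uniform(20, 80, n).round(1)
    panel["smoking"] = rng.choice(["yes", "no"], n, p=[0.25, 0.75])
    panel["center"] = rng.choice(["Lausanne", "Geneva", "Bern"], n, p=[0.4, 0.45, 0.15])
    panel["family"] = rng.integers(1, n // 2 + 1, n)
    rows = []
    for b, name in enumerate(names):
        side = "below" if name == "hdl" else "above"
        if b == 0:  # one sex-stratified cutoff to exercise the threshold table
            rows.append({"biomarker": name, "sex": "male", "cutoff": cutoffs[b] + 0.0,
                         "risk_side": side})
            rows.append({"biomarker": name, "sex": "female", "cutoff": cutoffs[b] + 0.0,
                         "risk_side": side})
        else:
            rows.append({"biomarker": name, "sex": "any", "cutoff": cutoffs[b],
                         "risk_side": side})
    thresholds = pd.DataFrame(rows)
    return panel, thresholds, pd.Series(k_true, index=samples)


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate the full synthetic input bundle plus its truth table."""
    rng = np.random.default_rng(config.seed)
    reference = generate_reference(config, rng)
    H = config.n_celltypes
    cts = CELL_TYPES[:H]
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    sexes = pd.Series(rng.choice(["female", "male"], n), index=samples)
    high_mask = np.zeros(n, dtype=bool)
    high_mask[rng.choice(n, size=config.n_high, replace=False)] = True
    groups = pd.Series(np.where(high_mask, "high", "low"), index=samples)
    high_samples = [s for s, m in zip(samples, high_mask) if m]

    panel, thresholds, k_true = _make_biomarkers(config, rng, samples, high_mask, sexes)

    W = rng.dirichlet(config.dirichlet_alpha, size=n)  # n × H
    proportions = pd.DataFrame(W, index=samples, columns=cts)

    # cell-level methylation: profiles + planted shifts, then mixed
    Z = np.repeat(reference.meth_profiles.to_numpy()[:, :, None], n, axis=2)  # j × H × n
    sample_pos = {s: i for i, s in enumerate(samples)}

    # planted pairs occupy dedicated non-signature genes and dedicated CpGs
    non_sig = [g for g in reference.gene_symbols if g not in set(reference.signature_genes)]
    planted_rows = []
    affected: dict[int, dict[str, list]] = {}
    planted_cpgs = []
    for idx, pair in enumerate(config.planted_pairs):
        cpg = reference.cpg_ids[idx]
        gene = non_sig[idx]
        if gene in set(reference.signature_genes):
            raise ValueError(f"planted pair {idx} collides with a signature gene")
        planted_cpgs.append((cpg, gene))
        h = cts.index(pair.cell_type)
        j = reference.cpg_ids.index(cpg)
        n_aff = max(2, int(round(pair.subset_frac * len(high_samples))))
        # anchor the unshifted mean mid-range so ± effect stays inside [0,1]
        Z[j, :, :] = 0.5
        if pair.state == "dual":
            # unequal subsets so the prevalence rule has a winner (hyper)
            sizes = {"hyper": n_aff, "hypo": max(2, n_aff - max(1, n_aff // 3))}
            resolved = "hyper"
        else:
            sizes = {pair.state: n_aff}
            resolved = pair.state
        chosen = list(rng.choice(high_samples, size=sum(sizes.values()), replace=False))
        affected[idx] = {}
        pos = 0
        for st, sz in sizes.items():
            subset = chosen[pos : pos + sz]
            pos += sz
            affected[idx][st] = subset
            sign = 1.0 if st == "hyper" else -1.0
            cols = [sample_pos[s] for s in subset]
            Z[j, h, cols] = np.clip(Z[j, h, cols] + sign * pair.effect_size, 0, 1)
        planted_rows.append({
            "pair_idx": idx, "cpg": cpg, "gene": gene, "cell_type": pair.cell_type,
            "mode": pair.mode, "state": pair.state,
            "effect_size": pair.effect_size, "expr_shift": pair.expr_shift,
            "subset_frac": pair.subset_frac,
            "direction": _direction_of(resolved, pair.mode),
        })

    bulk_meth = np.einsum("ih,jhi->ji", W, Z)
    if config.meth_noise_sd > 0:
        bulk_meth = bulk_meth + rng.normal(0, config.meth_noise_sd, bulk_meth.shape)
    bulk_meth = np.clip(bulk_meth, 0, 1)

    # chrX probes appended: sex-driven, cell-type independent
    chrx = np.empty((config.n_chrx_probes, n))
    for i, s in enumerate(samples):
        base = reference.chrx_female if sexes[s] == "female" else reference.chrx_male
        chrx[:, i] = np.clip(base + rng.normal(0, 0.02, config.n_chrx_probes), 0, 1)
    beta = pd.DataFrame(
        np.vstack([bulk_meth, chrx]),
        index=reference.cpg_ids + reference.chrx_ids,
        columns=samples,
    )

    # cell-level expression on log scale: profile × per-sample noise × shifts
    expr_prof = reference.expr_profiles.to_numpy()  # g × H
    E = expr_prof[:, :, None] * np.exp(
        rng.normal(0, config.expr_profile_sd, (config.n_genes, H, n))
    )
    for idx, pair in enumerate(config.planted_pairs):
        cpg, gene = planted_cpgs[idx]
        g = reference.gene_symbols.index(gene)
        h = cts.index(pair.cell_type)
        for st, subset in affected[idx].items():
            up = _direction_of(st, pair.mode) == "up"
            factor = np.exp((1.0 if up else -1.0) * pair.expr_shift * config.expr_profile_sd)
            cols = [sample_pos[s] for s in subset]
            E[g, h, cols] *= factor
    bulk_expr = np.einsum("ih,ghi->gi", W, E)
    if config.expr_noise_sd > 0:
        bulk_expr = bulk_expr * np.exp(rng.normal(0, config.expr_noise_sd, bulk_expr.shape))
    expression = pd.DataFrame(bulk_expr, index=reference.source_ids, columns=samples)

    # gene-ID map: a small fraction unmapped, never a planted or signature gene
    gene_map = pd.Series(reference.gene_symbols, index=reference.source_ids, dtype=object)
    protected = set(reference.signature_genes) | {g for _, g in planted_cpgs}
    candidates = [i for i, g in enumerate(reference.gene_symbols) if g not in protected]
    n_unmapped = int(config.unmapped_gene_frac * config.n_genes)
    if n_unmapped and candidates:
        drop = rng.choice(candidates, size=min(n_unmapped, len(candidates)), replace=False)
        gene_map.iloc[drop] = np.nan

    # probe annotation: autosomal linked genes, strata, blacklist
    linked = rng.choice(reference.gene_symbols, size=config.n_cpgs)
    for (cpg, gene) in planted_cpgs:
        linked[reference.cpg_ids.index(cpg)] = gene
    strata = rng.choice(STRATA, size=config.n_cpgs + config.n_chrx_probes, p=[0.7, 0.15, 0.15])
    chroms = [f"chr{rng.integers(1, 23)}" for _ in range(config.n_cpgs)] + ["X"] * config.n_chrx_probes
    blacklist = np.zeros(config.n_cpgs + config.n_chrx_probes, dtype=bool)
    protected_cpg_idx = {reference.cpg_ids.index(c) for c, _ in planted_cpgs}
    bl_candidates = [j for j in range(config.n_cpgs) if j not in protected_cpg_idx]
    if config.n_blacklist and bl_candidates:
        bl = rng.choice(bl_candidates, size=min(config.n_blacklist, len(bl_candidates)),
                        replace=False)
        blacklist[bl] = True
    annotation = pd.DataFrame({
        "chrom": chroms,
        "stratum": strata,
        "gene": list(linked) + [""] * config.n_chrx_probes,
        "blacklist": blacklist,
    }, index=reference.cpg_ids + reference.chrx_ids)

    # reported sex with planted mismatches
    reported = sexes.copy()
    mismatched = []
    if config.n_sex_mismatches:
        flip = rng.choice(samples, size=config.n_sex_mismatches, replace=False)
        for s in flip:
            reported[s] = "male" if sexes[s] == "female" else "female"
        mismatched = list(flip)
    panel["sex"] = reported.to_numpy()

    signature = reference.expr_profiles.loc[reference.signature_genes].copy()

    planted_df = pd.DataFrame(planted_rows, columns=[
        "pair_idx", "cpg", "gene", "cell_type", "mode", "state",
        "effect_size", "expr_shift", "subset_frac", "direction",
    ])
    truth = TruthTable(
        proportions=proportions,
        planted=planted_df,
        affected_samples=affected,
        sexes=sexes,
        mismatched_samples=mismatched,
        al_scores=k_true.astype(float),
        al_groups=groups,
        reference=reference,
    )
    return Cohort(
        beta=beta, expression=expression, panel=panel, thresholds=thresholds,
        annotation=annotation, gene_map=gene_map, signature=signature, truth=truth,
    )


def null_cohort(config: SimConfig) -> Cohort:
    """Same generator with an empty planted-pair table (type-I-error studies)."""
    return generate_cohort(replace(config, planted_pairs=()))


def generate_celltype_cohort(
    n_high: int = 126,
    n_low: int = 303,
    n_cpgs: int = 2000,
    planted_pairs: tuple = (),
    noise_sd: float = 0.05,
    expr_sd: float = 0.3,
    seed: int = 0,
):
    """One already-cell-resolved methylation/expression dataset with planted pairs.

    Bypasses mixing and deconvolution: the returned matrices play the role of
    one cell type's tensor slices, for isolated testing of the association
    stage. Returns (meth, expr, groups, annotation, truth_df).
    """
    rng = np.random.default_rng(seed)
    n = n_high + n_low
    samples = [f"S{i:04d}" for i in range(n)]
    groups = pd.Series(["high"] * n_high + ["low"] * n_low, index=samples)
    high_samples = samples[:n_high]
    cpgs = [f"cg{i:06d}" for i in range(n_cpgs)]
    genes = [f"GENE{i:05d}" for i in range(n_cpgs)]

    base = rng.uniform(0.25, 0.75, n_cpgs)
    meth = np.clip(base[:, None] + rng.normal(0, noise_sd, (n_cpgs, n)), 0, 1)
    log_mu = rng.normal(np.log(100), 0.5, n_cpgs)
    expr = np.exp(log_mu[:, None] + rng.normal(0, expr_sd, (n_cpgs, n)))

    rows = []
    for idx, pair in enumerate(planted_pairs):
        j = idx
        n_aff = max(2, int(round(pair.subset_frac * n_high)))
        if pair.state == "dual":
            sizes = {"hyper": n_aff, "hypo": max(2, n_aff - max(1, n_aff // 3))}
            resolved = "hyper"
        else:
            sizes = {pair.state: n_aff}
            resolved = pair.state
        chosen = list(rng.choice(high_samples, size=sum(sizes.values()), replace=False))
        meth[j, :] = np.clip(0.5 + rng.normal(0, noise_sd, n), 0, 1)
        pos = 0
        for st, sz in sizes.items():
            subset = chosen[pos : pos + sz]
            pos += sz
            cols = [samples.index(s) for s in subset]
            sign = 1.0 if st == "hyper" else -1.0
            meth[j, cols] = np.clip(meth[j, cols] + sign * pair.effect_size, 0, 1)
            up = _direction_of(st, pair.mode) == "up"
            expr[j, cols] *= np.exp((1.0 if up else -1.0) * pair.expr_shift * expr_sd)
        rows.append({
            "pair_idx": idx, "cpg": cpgs[j], "gene": genes[j],
            "mode": pair.mode, "state": pair.state,
            "direction": _direction_of(resolved, pair.mode),
        })
    meth_df = pd.DataFrame(meth, index=cpgs, columns=samples)
    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    annotation = pd.DataFrame({
        "chrom": ["chr1"] * n_cpgs, "stratum": ["typeII"] * n_cpgs,
        "gene": genes, "blacklist": [False] * n_cpgs,
    }, index=cpgs)
    truth_df = pd.DataFrame(rows, columns=["pair_idx", "cpg", "gene", "mode", "state", "direction"])
    return meth_df, expr_df, groups, annotation, truth_df
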