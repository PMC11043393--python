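"""Synthetic genomes with the statistical structure the pipeline assumes.

The generator produces, with ground truth attached to every record:

* a smooth replication-timing (RT) landscape per cell type over fixed-size
  bins, with a configurable constitutive (shared across cell types) vs
  dynamic (independently drawn) split;
* enhancers whose birth probability of being lineage-specific ("recent")
  increases with replication lateness, plus a multi-species mark matrix
  consistent with the recent/conserved labels under the >=2-species rule;
* element sequences whose GC content tracks RT, optionally with planted PWM
  instances (AT-rich motifs preferentially at late elements);
* population variants with a baseline derived-allele-frequency spectrum and a
  configurable excess of rare alleles at constrained motif positions;
* labeled transposable-element insertions (recent insertions biased late);
* matched healthy/tumor peak sets with RT-dependent gain/loss rates and
  per-element somatic mutation counts;
* an expression matrix with known per-gene tissue-specificity (tau).

Everything is deterministic given the config seed; each generator draws from
its own child stream so the outputs are independent but reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit, logit

from .core import ElementSet, MarkMatrix, ValidationError, VariantTable
from .motifs import tau as tau_index
from .timing import ReplicationTrack

_STREAMS = {
    "rt": 0,
    "enhancers": 1,
    "sequences": 2,
    "variants": 3,
    "te": 4,
    "cancer": 5,
    "expression": 6,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic genome; defaults are the study conditions.

    The genome is one synthetic chromosome tiled by ``bin_size`` RT bins
    (200 kb, matching the analysis grid). ``birth_rate_slope`` is the
    log-odds increase of an enhancer being recent per unit of replication
    lateness (-RT); the default gives recent enhancers roughly twice the
    frequency at late vs early domains. ``gc_slope`` couples sequence GC to
    RT on the logit scale. ``selection_rare_excess`` multiplies the
    rare:common odds of variants at constrained motif positions (1 = neutral).
    """

    genome_size: int = 20_000_000
    bin_size: int = 200_000
    chrom: str = "chr1"
    n_celltypes: int = 4
    rt_autocorr_length: int = 1_000_000
    dynamic_fraction: float = 0.3
    # enhancer history
    enhancers_per_bin: float = 20.0
    abundance_slope: float = 0.5  # enhancers are more abundant at early RT
    birth_rate_slope: float = 0.45
    recent_logit: float = -0.2  # baseline log-odds of "recent" at RT = 0
    n_species: int = 10  # focal + 9 comparison species
    conservation_decay: float = 0.5
    recent_other_prob: float = 0.3  # recent elements seen in <=1 other species
    force_k_other: int | None = None  # override: fixed mark count in other species
    element_len_mean: float = 1000.0
    element_len_sigma: float = 0.25
    # sequences
    base_gc: float = 0.41
    gc_slope: float = 0.08
    motif_plant_prob: float = 0.5
    motif_at_bias: float = 1.0
    # population variants
    variant_density: float = 0.01  # variants per bp of simulated footprint
    daf_spectrum: tuple[float, float, float] = (0.55, 0.20, 0.25)  # rare/mid/common
    selection_rare_excess: float = 1.0
    # transposable elements
    te_per_bin: float = 5.0
    te_recent_logit: float = -0.5
    te_rt_slope: float = 0.6
    # cancer peak sets
    cancer_gain_rate: float = 0.12
    cancer_loss_rate: float = 0.12
    cancer_rt_slope: float = 0.6
    somatic_rate_per_bp: float = 0.002
    somatic_rt_slope: float = 0.3
    somatic_turnover_multiplier: float = 2.0
    # expression
    n_genes: int = 300
    n_tissues: int = 4
    tau_targets: tuple[float, ...] = (0.1, 0.5, 0.9)
    expression_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size % self.bin_size:
            raise ValidationError("genome_size must be a multiple of bin_size")
        if not 0 <= self.dynamic_fraction <= 1:
            raise ValidationError("dynamic_fraction must be in [0,1]")
        if self.selection_rare_excess < 1:
            raise ValidationError("selection_rare_excess must be >= 1")
        if abs(sum(self.daf_spectrum) - 1.0) > 1e-9 or min(self.daf_spectrum) < 0:
            raise ValidationError("daf_spectrum must be a probability vector")

    @property
    def n_bins(self) -> int:
        return self.genome_size // self.bin_size

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass
class SyntheticTruth:
    """Ground truth written by the generators; read only by test code."""

    bin_classes: pd.DataFrame | None = None  # chrom, start, end, true_class
    element_ages: pd.DataFrame | None = None  # id, true_age
    variant_flags: pd.DataFrame | None = None  # chrom, pos, constrained
    cancer_fates: pd.DataFrame | None = None  # id, true_fate
    gene_tau: pd.DataFrame | None = None  # gene, target_tau
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# replication-timing landscape


def _smooth_field(rng: np.random.Generator, n_bins: int, sigma_bins: float) -> np.ndarray:
    noise = rng.standard_normal(n_bins)
    if sigma_bins > 0:
        noise = gaussian_filter1d(noise, sigma=sigma_bins, mode="reflect")
    return noise


def simulate_rt_landscape(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[ReplicationTrack], SyntheticTruth]:
    """Smoothed Gaussian RT landscape per cell type, z-scored per track.

    A contiguous-ish constitutive mask (1 - dynamic_fraction of bins, from a
    thresholded smooth field) shares the base landscape across cell types;
    dynamic bins draw independently per cell type. Truth records the
    generating class of each bin: early/late from the shared base field by
    the 0.5/-0.5 thresholds, dynamic otherwise.
    """
    rng = rng or config.rng("rt")
    n = config.n_bins
    sigma = config.rt_autocorr_length / config.bin_size
    base = _smooth_field(rng, n, sigma)
    base = (base - base.mean()) / base.std(ddof=0)
    mask_field = _smooth_field(rng, n, sigma)
    if config.dynamic_fraction <= 0:
        shared = np.ones(n, dtype=bool)
    elif config.dynamic_fraction >= 1:
        shared = np.zeros(n, dtype=bool)
    else:
        thr = np.quantile(np.abs(mask_field), config.dynamic_fraction)
        shared = np.abs(mask_field) >= thr

    starts = np.arange(n) * config.bin_size
    ends = starts + config.bin_size
    tracks = []
    for ct in range(config.n_celltypes):
        own = _smooth_field(rng, n, sigma)
        own = (own - own.mean()) / own.std(ddof=0)
        vals = np.where(shared, base, own)
        vals = (vals - vals.mean()) / vals.std(ddof=0)
        tracks.append(
            ReplicationTrack(
                f"celltype_{ct + 1}",
                pd.DataFrame(
                    {"chrom": config.chrom, "start": starts, "end": ends, "value": vals}
                ),
            )
        )
    true_class = np.where(
        shared & (base > 0.5), "early", np.where(shared & (base < -0.5), "late", "dynamic")
    )
    truth = SyntheticTruth(
        bin_classes=pd.DataFrame(
            {
                "chrom": config.chrom,
                "start": starts,
                "end": ends,
                "true_class": true_class,
                "shared": shared,
                "base_rt": base,
            }
        )
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# enhancer history


def _place_elements(
    config: SimulationConfig,
    rng: np.random.Generator,
    counts_per_bin: np.ndarray,
    prefix: str,
) -> pd.DataFrame:
    """Place non-overlapping elements bin by bin on a slotted grid.

    Slots of 3 kb with lengths capped at 2.4 kb guarantee non-overlap, which
    keeps downstream pair matching (cancer fates) unambiguous.
    """
    slot = 3000
    slots_per_bin = config.bin_size // slot
    rows = []
    eid = 0
    for b, count in enumerate(counts_per_bin):
        count = min(int(count), slots_per_bin)
        if count == 0:
            continue
        chosen = rng.choice(slots_per_bin, size=count, replace=False)
        chosen.sort()
        lengths = np.clip(
            rng.lognormal(np.log(config.element_len_mean), config.element_len_sigma, count),
            300,
            2400,
        ).astype(int)
        jitter = rng.integers(0, slot - lengths)
        starts = b * config.bin_size + chosen * slot + jitter
        for s, ln in zip(starts, lengths):
            rows.append((config.chrom, int(s), int(s + ln), f"{prefix}{eid:06d}", b))
            eid += 1
    if not rows:
        raise ValidationError(
            "zero elements generated; increase genome_size or the per-bin rate"
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "bin"])


def simulate_enhancer_history(
    config: SimulationConfig,
    rt: ReplicationTrack,
    rng: np.random.Generator | None = None,
) -> tuple[ElementSet, MarkMatrix, SyntheticTruth]:
    """Enhancers with RT-dependent recent/conserved ages and a mark matrix.

    Per-bin expected abundance is proportional to exp(abundance_slope * RT)
    (enhancers are most numerous at early domains) while the probability a
    born enhancer is recent follows a logistic in replication lateness:
    logit P(recent) = recent_logit + birth_rate_slope * (-RT). The mark
    matrix presents the focal species everywhere; conserved elements carry
    marks in >=2 other species (count decaying geometrically by
    conservation_decay), recent elements in <=1.
    """
    rng = rng or config.rng("enhancers")
    v = rt.values
    lam = np.exp(config.abundance_slope * v)
    lam = config.enhancers_per_bin * lam / lam.mean()
    counts = rng.poisson(lam)
    df = _place_elements(config, rng, counts, "enh")
    bin_rt = v[df["bin"].to_numpy()]
    p_recent = expit(config.recent_logit + config.birth_rate_slope * (-bin_rt))
    recent = rng.random(len(df)) < p_recent

    n_other = config.n_species - 1
    if config.force_k_other is not None:
        k_other = np.full(len(df), min(config.force_k_other, n_other))
    else:
        if not 0 < config.conservation_decay <= 1:
            raise ValidationError("conservation_decay must be in (0,1] unless force_k_other set")
        k_cons = np.minimum(1 + rng.geometric(config.conservation_decay, len(df)), n_other)
        k_rec = (rng.random(len(df)) < config.recent_other_prob).astype(int)
        k_other = np.where(recent, k_rec, k_cons)

    present = np.zeros((len(df), config.n_species), dtype=bool)
    present[:, 0] = True
    for i, k in enumerate(k_other):
        if k > 0:
            others = rng.choice(n_other, size=int(k), replace=False)
            present[i, 1 + others] = True

    species = ["focal"] + [f"species_{j}" for j in range(1, config.n_species)]
    marks = MarkMatrix(list(df["id"]), species, present)
    truth = SyntheticTruth(
        element_ages=pd.DataFrame(
            {"id": df["id"], "true_age": np.where(recent, "recent", "conserved")}
        )
    )
    elements = ElementSet(df.drop(columns=["bin"]))
    return elements, marks, truth


# ---------------------------------------------------------------------------
# sequences


def simulate_sequences(
    config: SimulationConfig,
    elements: ElementSet,
    rt: ReplicationTrack,
    pwms=None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Element sequences with RT-coupled GC and optionally planted motifs.

    Per-element GC probability is logistic(logit(base_gc) + gc_slope * RT).
    When PWMs are supplied, a fraction of elements receives one instance
    sampled from a PWM chosen with weight exp(motif_at_bias * (-RT) *
    (at_fraction - 0.5)): AT-rich motifs land preferentially at late
    elements. Returns the sequences and a planted-instance table
    (element id, genomic start/end, motif id) usable as constrained motif
    positions downstream.
    """
    import warnings as _warnings

    rng = rng or config.rng("sequences")
    from .timing import assign_element_rt

    if "rt" not in elements.df.columns:
        elements = assign_element_rt(elements, rt)
    df = elements.df
    gc = expit(logit(config.base_gc) + config.gc_slope * df["rt"].to_numpy(dtype=float))
    gc = np.where(np.isnan(gc), config.base_gc, gc)
    sequences: dict[str, str] = {}
    planted = []
    base_arr = np.array(list("ACGT"))
    for i, row in enumerate(df.itertuples(index=False)):
        length = row.end - row.start
        p = np.array([(1 - gc[i]) / 2, gc[i] / 2, gc[i] / 2, (1 - gc[i]) / 2])
        seq = rng.choice(base_arr, size=length, p=p)
        if pwms and rng.random() < config.motif_plant_prob:
            usable = [p_ for p_ in pwms if p_.length <= length]
            if not usable:
                _warnings.warn(
                    f"all motifs longer than element {row.id}; skipped planting",
                    RuntimeWarning,
                    stacklevel=2,
                )
            else:
                at_frac = np.array([1.0 - p_.freqs[:, [1, 2]].sum(axis=1).mean() for p_ in usable])
                lateness = -df["rt"].iloc[i] if np.isfinite(df["rt"].iloc[i]) else 0.0
                w = np.exp(config.motif_at_bias * lateness * (at_frac - 0.5))
                pwm = usable[rng.choice(len(usable), p=w / w.sum())]
                offset = int(rng.integers(0, length - pwm.length + 1))
                inst = [base_arr[rng.choice(4, p=col / col.sum())] for col in pwm.freqs]
                seq[offset : offset + pwm.length] = inst
                planted.append(
                    (row.id, row.chrom, row.start + offset, row.start + offset + pwm.length, pwm.id)
                )
        sequences[row.id] = "".join(seq)
    planted_df = pd.DataFrame(
        planted, columns=["element_id", "chrom", "start", "end", "motif_id"]
    )
    return sequences, planted_df


# ---------------------------------------------------------------------------
# population variants


def simulate_population_variants(
    config: SimulationConfig,
    regions: ElementSet,
    motif_positions: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[VariantTable, SyntheticTruth]:
    """Population variants with a baseline DAF spectrum over a region footprint.

    Variants are placed uniformly over the merged footprint of ``regions`` at
    ``variant_density`` per bp. At constrained positions (inside
    ``motif_positions`` intervals) the rare:common odds are multiplied by
    ``selection_rare_excess`` while the intermediate-frequency mass is kept.
    """
    rng = rng or config.rng("variants")
    from .core import merge_intervals

    merged = merge_intervals(regions.df[["chrom", "start", "end"]])
    seg_len = (merged["end"] - merged["start"]).to_numpy()
    total = int(seg_len.sum())
    n = rng.poisson(config.variant_density * total)
    if n == 0:
        return (
            VariantTable(pd.DataFrame(columns=["chrom", "pos", "daf"])),
            SyntheticTruth(variant_flags=pd.DataFrame(columns=["chrom", "pos", "constrained"])),
        )
    offsets = rng.integers(0, total, size=n)
    cum = np.concatenate([[0], np.cumsum(seg_len)])
    seg = np.searchsorted(cum, offsets, side="right") - 1
    pos = merged["start"].to_numpy()[seg] + (offsets - cum[seg])
    chrom = merged["chrom"].to_numpy()[seg]

    constrained = np.zeros(n, dtype=bool)
    if motif_positions is not None and len(motif_positions):
        mm = merge_intervals(motif_positions[["chrom", "start", "end"]])
        for c, sub in mm.groupby("chrom"):
            sel = chrom == c
            if not sel.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            idx = np.searchsorted(starts, pos[sel], side="right") - 1
            inside = (idx >= 0) & (pos[sel] < ends[np.maximum(idx, 0)])
            constrained[np.flatnonzero(sel)[inside]] = True

    pr, pm, pc = config.daf_spectrum
    s = config.selection_rare_excess
    odds = (pr / pc) * s
    mass = pr + pc
    probs_constrained = np.array([mass * odds / (1 + odds), pm, mass / (1 + odds)])
    probs_base = np.array([pr, pm, pc])
    u = rng.random(n)
    probs = np.where(constrained[:, None], probs_constrained[None, :], probs_base[None, :])
    cls = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)  # 0 rare, 1 mid, 2 common
    daf = np.empty(n)
    daf[cls == 0] = rng.uniform(1e-4, 0.0149, size=int((cls == 0).sum()))
    daf[cls == 1] = rng.uniform(0.0151, 0.0499, size=int((cls == 1).sum()))
    daf[cls == 2] = rng.uniform(0.0501, 0.5, size=int((cls == 2).sum()))

    table = VariantTable(pd.DataFrame({"chrom": chrom, "pos": pos, "daf": daf}))
    truth = SyntheticTruth(
        variant_flags=pd.DataFrame({"chrom": chrom, "pos": pos, "constrained": constrained})
    )
    return table, truth


# ---------------------------------------------------------------------------
# transposable elements


def simulate_te_insertions(
    config: SimulationConfig,
    rt: ReplicationTrack,
    rng: np.random.Generator | None = None,
) -> ElementSet:
    """Labeled TE insertion intervals; recent insertions are biased late."""
    rng = rng or config.rng("te")
    v = rt.values
    counts = rng.poisson(np.full(config.n_bins, config.te_per_bin))
    df = _place_elements(config, rng, counts, "te")
    p_recent = expit(config.te_recent_logit + config.te_rt_slope * (-v[df["bin"].to_numpy()]))
    age = np.where(rng.random(len(df)) < p_recent, "recent", "ancestral")
    return ElementSet(df.drop(columns=["bin"]).assign(te_age=age))


# ---------------------------------------------------------------------------
# cancer peak sets


def simulate_cancer_peaks(
    config: SimulationConfig,
    rt: ReplicationTrack,
    rng: np.random.Generator | None = None,
) -> tuple[ElementSet, ElementSet, VariantTable, SyntheticTruth]:
    """Matched healthy/tumor peak sets with RT-dependent gain/loss fates.

    Gain and loss probabilities scale with exp(cancer_rt_slope * lateness);
    unchanged peaks appear identically in both sets. Somatic mutation counts
    per element are Poisson with rate proportional to width times
    (1 + somatic_rt_slope * lateness), doubled (by default) at gained and
    lost elements.
    """
    rng = rng or config.rng("cancer")
    v = rt.values
    counts = rng.poisson(np.full(config.n_bins, config.enhancers_per_bin))
    df = _place_elements(config, rng, counts, "cpk")
    lateness = -v[df["bin"].to_numpy()]
    p_gain = np.clip(config.cancer_gain_rate * np.exp(config.cancer_rt_slope * lateness), 0, 0.45)
    p_loss = np.clip(config.cancer_loss_rate * np.exp(config.cancer_rt_slope * lateness), 0, 0.45)
    u = rng.random(len(df))
    fate = np.where(u < p_gain, "gained", np.where(u < p_gain + p_loss, "lost", "unchanged"))

    widths = (df["end"] - df["start"]).to_numpy()
    mult = np.where(fate == "unchanged", 1.0, config.somatic_turnover_multiplier)
    rate = (
        config.somatic_rate_per_bp
        * widths
        * np.maximum(1.0 + config.somatic_rt_slope * lateness, 0.1)
        * mult
    )
    n_mut = rng.poisson(rate)
    mut_rows = []
    for row, k in zip(df.itertuples(index=False), n_mut):
        if k:
            pos = rng.integers(row.start, row.end, size=int(k))
            mut_rows.extend((row.chrom, int(p), 0.0) for p in pos)
    somatic = VariantTable(pd.DataFrame(mut_rows, columns=["chrom", "pos", "daf"]))

    keep = df.drop(columns=["bin"])
    healthy = ElementSet(keep[np.isin(fate, ["unchanged", "lost"])])
    tumor = ElementSet(keep[np.isin(fate, ["unchanged", "gained"])])
    truth = SyntheticTruth(
        cancer_fates=pd.DataFrame({"id": df["id"], "true_fate": fate}),
        extras={"n_mutations": pd.DataFrame({"id": df["id"], "n_mutations": n_mut})},
    )
    return healthy, tumor, somatic, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Genes x tissues expression with known tissue-specificity targets.

    Each gene draws a target tau class; its row has one maximal tissue at 1
    and the others at (1 - tau), which realizes the target exactly before a
    small uniform noise perturbation. Rows are scaled by a lognormal factor
    (tau is scale-invariant).
    """
    rng = rng or config.rng("expression")
    n_t = config.n_tissues
    targets = rng.choice(config.tau_targets, size=config.n_genes)
    mat = np.empty((config.n_genes, n_t))
    for i, t in enumerate(targets):
        row = np.full(n_t, 1.0 - t)
        row[rng.integers(0, n_t)] = 1.0
        row = row + rng.uniform(-config.expression_noise, config.expression_noise, n_t)
        mat[i] = np.clip(row, 0, None) * rng.lognormal(2.0, 0.5)
    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    expr = pd.DataFrame(mat, index=genes, columns=[f"tissue_{j + 1}" for j in range(n_t)])
    realized = np.array([tau_index(mat[i]) for i in range(config.n_genes)])
    truth = SyntheticTruth(
        gene_tau=pd.DataFrame({"gene": genes, "target_tau": targets, "realized_tau": realized})
    )
    return expr, truth


# ---------------------------------------------------------------------------
# bundle


def simulate_all(config: SimulationConfig, pwms=None) -> dict:
    """Run every generator off one config; returns a named bundle."""
    from .timing import mean_track

    tracks, rt_truth = simulate_rt_landscape(config)
    germline = mean_track(tracks, cell_type="germline_mean")
    elements, marks, age_truth = simulate_enhancer_history(config, germline)
    sequences, planted = simulate_sequences(config, elements, germline, pwms=pwms)
    variants, var_truth = simulate_population_variants(
        config, elements, planted if len(planted) else None
    )
    tes = simulate_te_insertions(config, germline)
    healthy, tumor, somatic, cancer_truth = simulate_cancer_peaks(config, germline)
    expression, expr_truth = simulate_expression(config)
    return {
        "config": config,
        "tracks": tracks,
        "germline_mean": germline,
        "elements": elements,
        "marks": marks,
        "sequences": sequences,
        "planted_motifs": planted,
        "variants": variants,
        "te_insertions": tes,
        "cancer_healthy": healthy,
        "cancer_tumor": tumor,
        "somatic": somatic,
        "expression": expression,
        "truth": SyntheticTruth(
            bin_classes=rt_truth.bin_classes,
            element_ages=age_truth.element_ages,
            variant_flags=var_truth.variant_flags,
            cancer_fates=cancer_truth.cancer_fates,
            gene_tau=expr_truth.gene_tau,
            extras=cancer_truth.extras,
        ),
    }


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
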