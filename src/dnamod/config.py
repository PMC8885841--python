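"""Simulation and pipeline configuration.

All simulator behaviour is driven by a single :class:`SimConfig` tree of
dataclasses.  The defaults describe a small (200 kb) genome whose methylome
has the structure the analysis stages are designed to detect: asymmetric
single-strand 4mC concentrated at CpG/CpA sites inside intact transposable
elements (TEs) and tandem repeats with fractions massed at 1.0, and 6mA at
GA-context adenines genome-wide with a broader (Beta) fraction distribution.

Coordinates are 0-based half-open throughout the package; converters in
:mod:`dnamod.io` handle 1-based GFF3 on the way in and out.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is out of its valid domain."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class TEFamilyConfig:
    """One TE family: a consensus and counts of copies per integrity class.

    Full copies span >=95% of the consensus, medium copies 50-90%, short
    fragments 10-50% (copies are 5'-anchored consensus prefixes).
    """

    name: str = "Gypsy"
    consensus_length: int = 3000
    n_full: int = 3
    n_medium: int = 3
    n_short: int = 12

    def validate(self) -> None:
        _check(self.consensus_length > 0, "consensus_length must be > 0")
        _check(min(self.n_full, self.n_medium, self.n_short) >= 0,
               "copy counts must be >= 0")


@dataclass
class GeneStructureConfig:
    n_exons_mean: float = 4.0
    exon_length_mean: int = 250
    intron_length_mean: int = 120
    utr5_length: int = 100
    utr3_length: int = 200
    #: bp upstream of the TSS annotated as promoter
    promoter_span: int = 2000
    #: fraction of genes flagged TE-derived; such genes carry a TE insertion
    te_gene_fraction: float = 0.1
    #: length of the TE insertion carried by TE-derived genes; at the
    #: default family consensus this is a medium-to-full integrity copy
    te_gene_insert_length: int = 2000
    te_gene_insert_family: int = 0

    def validate(self) -> None:
        _check(self.n_exons_mean >= 1, "n_exons_mean must be >= 1")
        for name in ("exon_length_mean", "intron_length_mean", "utr5_length",
                     "utr3_length", "promoter_span", "te_gene_insert_length"):
            _check(getattr(self, name) > 0, f"{name} must be > 0")
        _check(0.0 <= self.te_gene_fraction <= 1.0,
               "te_gene_fraction must be in [0, 1]")


@dataclass
class TandemRepeatConfig:
    n_arrays: int = 4
    unit_length: int = 25
    array_length_min: int = 400
    array_length_max: int = 1200

    def validate(self) -> None:
        _check(self.n_arrays >= 0, "n_arrays must be >= 0")
        _check(self.unit_length > 0, "unit_length must be > 0")
        _check(0 < self.array_length_min <= self.array_length_max,
               "array length range invalid")


@dataclass
class Meth4mCConfig:
    """Planting rules for N4-methylcytosine.

    Eligible positions are cytosines (either strand) inside the target
    feature classes, weighted by the dinucleotide context (favouring CpG and
    CpA) and by an exponential decay from the TE 5' boundary.
    """

    target_feature_classes: tuple[str, ...] = (
        "te_full", "te_medium", "tandem_repeat")
    #: expected planted sites per eligible cytosine
    site_rate: float = 0.15
    context_weights: dict[str, float] = field(
        default_factory=lambda: {"CG": 8.0, "CA": 4.0, "CC": 1.0, "CT": 1.0})
    te_5prime_decay_bp: float = 1000.0
    #: per-copy weight ~ integrity**power: intact (near full-length) copies
    #: are the preferred targets
    integrity_weight_power: float = 2.0
    #: point mass of the fraction distribution at 1.0
    fully_methylated_prob: float = 0.58
    #: Beta(a, b) for the remaining (non-fully-methylated) sites
    fraction_beta: tuple[float, float] = (6.0, 1.5)
    #: probability that an eligible TE copy / repeat carries any 4mC at all
    copy_methylation_prob: float = 1.0

    def validate(self) -> None:
        _check(0.0 <= self.site_rate <= 1.0, "site_rate must be in [0, 1]")
        _check(all(w >= 0 for w in self.context_weights.values()),
               "context weights must be >= 0")
        _check(self.te_5prime_decay_bp > 0, "te_5prime_decay_bp must be > 0")
        _check(self.integrity_weight_power >= 0,
               "integrity_weight_power must be >= 0")
        _check(0.0 <= self.fully_methylated_prob <= 1.0,
               "fully_methylated_prob must be in [0, 1]")
        _check(0.0 <= self.copy_methylation_prob <= 1.0,
               "copy_methylation_prob must be in [0, 1]")
        a, b = self.fraction_beta
        _check(a > 0 and b > 0, "fraction_beta parameters must be > 0")


@dataclass
class Meth6mAConfig:
    """Planting rules for N6-methyladenine (genome-wide, GA-context biased)."""

    site_rate: float = 0.008
    #: multiplicative weight when the preceding base is G (GA doublet)
    prev_g_weight: float = 6.0
    #: multiplicative weight when the following base is A (GAA-type triplet)
    next_a_weight: float = 2.0
    fully_methylated_prob: float = 0.05
    fraction_beta: tuple[float, float] = (5.0, 2.0)

    def validate(self) -> None:
        _check(0.0 <= self.site_rate <= 1.0, "site_rate must be in [0, 1]")
        _check(self.prev_g_weight >= 0 and self.next_a_weight >= 0,
               "context weights must be >= 0")
        _check(0.0 <= self.fully_methylated_prob <= 1.0,
               "fully_methylated_prob must be in [0, 1]")
        a, b = self.fraction_beta
        _check(a > 0 and b > 0, "fraction_beta parameters must be > 0")


@dataclass
class KineticsConfig:
    """Polymerase-kinetics simulation (per-pass inter-pulse durations).

    Per-pass IPDs are log-normal; modification multiplies the median IPD by
    ``ipd_multiplier``.  At a site with fraction f each pass is modified
    independently with probability f.
    """

    mean_passes: float = 25.0
    sigma_log: float = 0.4
    ipd_multiplier: float = 3.0
    #: unmodified background sites added to the table (desk-scale stand-in
    #: for testing every genomic position)
    n_background_sites: int = 10000
    #: "model" = in-silico control (per-site log-mean); "sampled" = draw
    #: control observations
    control_mode: str = "model"
    control_passes: int = 50

    def validate(self) -> None:
        _check(self.mean_passes >= 0, "mean_passes must be >= 0")
        _check(self.sigma_log > 0, "sigma_log must be > 0")
        _check(self.ipd_multiplier > 0, "ipd_multiplier must be > 0")
        _check(self.n_background_sites >= 0, "n_background_sites >= 0")
        _check(self.control_mode in ("model", "sampled"),
               "control_mode must be 'model' or 'sampled'")
        _check(self.control_passes >= 2, "control_passes must be >= 2")


@dataclass
class DipConfig:
    """MeDIP/DIP-seq: fragmentation, antibody capture, 5'-prefix reads."""

    fragment_length_min: int = 200
    fragment_length_max: int = 400
    read_length: int = 50
    #: capture weight added per covered methyl mark (scaled by its fraction);
    #: unmethylated fragments carry weight ``background_weight``
    capture_enrichment: float = 10.0
    background_weight: float = 1.0
    library_size: int = 50000
    #: candidate fragments drawn per retained read
    oversample: int = 4

    def validate(self) -> None:
        _check(0 < self.fragment_length_min <= self.fragment_length_max,
               "fragment length range invalid")
        _check(0 < self.read_length <= self.fragment_length_min,
               "read_length must be in (0, fragment_length_min]")
        _check(self.capture_enrichment >= 0, "capture_enrichment must be >= 0")
        _check(self.background_weight > 0, "background_weight must be > 0")
        _check(self.library_size >= 0, "library_size must be >= 0")
        _check(self.oversample >= 1, "oversample must be >= 1")


@dataclass
class ChipConfig:
    """ChIP-seq: bimodal H3K4me3 at TSS of expressed genes; H3K9/27me3 over
    TE bodies with flanking spread; uniform background elsewhere."""

    read_length: int = 75
    fragment_length: int = 200
    library_size: int = 50000
    background_fraction: float = 0.3
    #: bimodal TSS peak offsets (bp) and SD for H3K4me3 fragment centres
    tss_offset: int = 300
    tss_sd: float = 150.0
    #: H3K9me3/H3K27me3 spread beyond TE bodies
    te_spread: int = 500

    def validate(self) -> None:
        _check(self.read_length > 0, "read_length must be > 0")
        _check(self.fragment_length >= self.read_length,
               "fragment_length must be >= read_length")
        _check(self.library_size >= 0, "library_size must be >= 0")
        _check(0.0 <= self.background_fraction <= 1.0,
               "background_fraction must be in [0, 1]")
        _check(self.tss_sd > 0, "tss_sd must be > 0")
        _check(self.te_spread >= 0, "te_spread must be >= 0")


@dataclass
class RnaseqConfig:
    """RNA-seq: multinomial exonic reads; expression couples to the marks.

    Per-gene rate = log-normal baseline x exonic length, multiplied by
    ``repression_4mC`` for TE-derived genes carrying 4mC and by
    ``activation_6mA`` for genes with 6mA within ``window`` bp.
    """

    library_size: int = 200000
    read_length: int = 50
    baseline_sigma_log: float = 1.0
    repression_4mC: float = 0.25
    activation_6mA: float = 2.0
    window: int = 500

    def validate(self) -> None:
        _check(self.library_size >= 0, "library_size must be >= 0")
        _check(self.read_length > 0, "read_length must be > 0")
        _check(self.baseline_sigma_log > 0, "baseline_sigma_log must be > 0")
        _check(self.repression_4mC > 0, "repression_4mC must be > 0")
        _check(self.activation_6mA > 0, "activation_6mA must be > 0")
        _check(self.window >= 0, "window must be >= 0")


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 200000
    n_contigs: int = 2
    gc_content: float = 0.31
    n_genes: int = 40
    #: probability that the base following a C in a TE consensus is G.
    #: TE targets of the N4-cytosine methyltransferase are CpG-containing,
    #: so consensus sequences carry more CpG than the genome background.
    te_consensus_cpg_boost: float = 0.3
    gene_structure: GeneStructureConfig = field(
        default_factory=GeneStructureConfig)
    te_families: list[TEFamilyConfig] = field(default_factory=lambda: [
        TEFamilyConfig("Gypsy", 3000, 3, 3, 12),
        TEFamilyConfig("LINE", 2400, 3, 3, 10),
    ])
    tandem_repeats: TandemRepeatConfig = field(
        default_factory=TandemRepeatConfig)
    meth_4mC: Meth4mCConfig = field(default_factory=Meth4mCConfig)
    meth_6mA: Meth6mAConfig = field(default_factory=Meth6mAConfig)
    #: target fraction of modified positions that belong to a symmetric
    #: (both-strand) pair; methylation is mostly asymmetric so this is small
    symmetric_fraction: float = 0.1
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    dip: DipConfig = field(default_factory=DipConfig)
    chip: ChipConfig = field(default_factory=ChipConfig)
    rnaseq: RnaseqConfig = field(default_factory=RnaseqConfig)

    def validate(self) -> None:
        _check(self.genome_length > 0, "genome_length must be > 0")
        _check(self.n_contigs > 0, "n_contigs must be > 0")
        _check(0.0 < self.gc_content < 1.0, "gc_content must be in (0, 1)")
        _check(0.0 <= self.te_consensus_cpg_boost < 1.0,
               "te_consensus_cpg_boost must be in [0, 1)")
        _check(self.n_genes >= 0, "n_genes must be >= 0")
        _check(0.0 <= self.symmetric_fraction <= 1.0,
               "symmetric_fraction must be in [0, 1]")
        self.gene_structure.validate()
        for fam in self.te_families:
            fam.validate()
        self.tandem_repeats.validate()
        self.meth_4mC.validate()
        self.meth_6mA.validate()
        self.kinetics.validate()
        self.dip.validate()
        self.chip.validate()
        self.rnaseq.validate()


_NESTED = {
    "gene_structure": GeneStructureConfig,
    "tandem_repeats": TandemRepeatConfig,
    "meth_4mC": Meth4mCConfig,
    "meth_6mA": Meth6mAConfig,
    "kinetics": KineticsConfig,
    "dip": DipConfig,
    "chip": ChipConfig,
    "rnaseq": RnaseqConfig,
}


def config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key in ("fraction_beta",):
        d["meth_4mC"][key] = list(d["meth_4mC"][key])
        d["meth_6mA"][key] = list(d["meth_6mA"][key])
    for fam in d["te_families"]:
        pass  # already plain dicts
    d["meth_4mC"]["target_feature_classes"] = list(
        d["meth_4mC"]["target_feature_classes"])
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    kwargs = {}
    for key, val in d.items():
        if key in _NESTED:
            sub = dict(val)
            if "fraction_beta" in sub:
                sub["fraction_beta"] = tuple(sub["fraction_beta"])
            if "target_feature_classes" in sub:
                sub["target_feature_classes"] = tuple(
                    sub["target_feature_classes"])
            kwargs[key] = _NESTED[key](**sub)
        elif key == "te_families":
            kwargs[key] = [TEFamilyConfig(**f) for f in val]
        else:
            kwargs[key] = val
    cfg = SimConfig(**kwargs)
    cfg.validate()
    return cfg


def save_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
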