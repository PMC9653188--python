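"""Synthetic breeding-program genotype and phenotype generator.

Emulates the structure of a national cereal breeding population: several
hundred to ~1,800 mostly inbred accessions contributed by regional breeding
stations, genotyped on a genome-tiling marker panel, with polygenic traits
whose location and scale shift between stations and harvest years.

The genetic model is deliberately lightweight: station founder allele
frequencies drift from a common ancestral frequency under a Balding-Nichols
model with divergence ``F``; accessions arise from crosses between two inbred
founders of the same station followed by several selfing generations, with
crossovers placed by the Haldane map function (no interference); residual
heterozygosity then halves each selfing generation.  This plants realistic
station-level population structure (for PCA), distance-dependent LD (for decay
analysis), and MAF heterogeneity along chromosomes — it does not model
mutation, migration between stations, or selection.

All randomness flows from ``SimConfig.seed``; every output is
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix

#: breeding-station codes used for synthetic accession metadata
STATION_CODES = ("TARC", "CARC", "NAES", "TAES", "NICS", "WARC", "FARC", "KARC")

#: reference chromosome sizes in Mb (barley-like 7-chromosome genome)
BARLEY_CHROM_SIZES_MB = (558.5, 768.1, 699.7, 647.1, 670.0, 583.4, 657.2)
BARLEY_CHROM_NAMES = ("1H", "2H", "3H", "4H", "5H", "6H", "7H")


@dataclass(frozen=True)
class TraitSpec:
    """One polygenic trait: QTL count, heritability, group-shift magnitudes."""

    name: str
    n_qtl: int = 100
    h2: float = 0.5
    #: location-shift magnitudes, in units of the trait's within-group
    #: phenotypic SD (the breeding-value scale is arbitrary)
    station_effect_sd: float = 1.0
    year_effect_sd: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if self.h2 == 1.0 and self.n_qtl == 0:
            raise ValueError("h2 = 1 requires at least one QTL")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic breeding population.

    Defaults describe a barley-like program: 7 chromosomes at published
    reference sizes, a 768-marker panel, 1,000 accessions from 8 stations over
    harvest years 2018/2019, Balding-Nichols divergence F = 0.08 between
    station founder pools, 8 founders per station, 6 selfing generations
    (advanced inbred lines; residual heterozygosity ~ 2^-6), an effective
    1 cM/Mb recombination rate, 2% missing calls at random, and ~20% of
    amplicons carrying a secondary polymorphism.
    """

    chrom_names: tuple = BARLEY_CHROM_NAMES
    chrom_sizes_mb: tuple = BARLEY_CHROM_SIZES_MB
    n_markers: int = 768
    n_accessions: int = 1000
    n_stations: int = 8
    station_codes: tuple = STATION_CODES
    fst: float = 0.08
    founders_per_station: int = 8
    selfing_generations: int = 6
    #: effective rate; compresses many breeding cycles into the few simulated
    #: meioses so LD decays over tens of Mb as in real breeding panels
    recomb_rate_cM_per_mb: float = 1.0
    missing_rate: float = 0.02
    position_jitter: float = 0.4
    group_scale_sd: float = 0.15
    ancestral_beta: tuple = (0.8, 0.8)
    extra_poly_mean: float = 0.24
    traits: tuple = (TraitSpec("TGW"), TraitSpec("GPC", h2=0.4))
    years: tuple = (2018, 2019)
    seed: int = 0

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_sizes_mb):
            raise ValueError("chrom_names and chrom_sizes_mb lengths differ")
        if sum(self.chrom_sizes_mb) <= 0:
            raise ValueError("total chromosome size must be positive")
        if self.n_markers < 2 * len(self.chrom_names):
            raise ValueError("need at least 2 markers per chromosome")
        if self.n_stations > len(self.station_codes):
            raise ValueError("not enough station codes for n_stations")


def barley_like(**overrides) -> SimConfig:
    """Barley-like preset: 7 chromosomes, 768 markers, 1,000 accessions."""
    return replace(SimConfig(), **overrides)


def wheat_like(**overrides) -> SimConfig:
    """Wheat-like preset: 21 chromosomes, 960 markers, 1,800 accessions."""
    names = tuple(f"{i}{g}" for g in "ABD" for i in range(1, 8))
    sizes = tuple(float(s) for s in (594.1, 780.8, 750.8, 744.6, 709.8, 618.1, 736.7,
                                     689.9, 801.3, 830.8, 673.6, 713.1, 721.0, 750.6,
                                     495.5, 651.9, 615.6, 509.9, 566.1, 473.6, 638.7))
    cfg = SimConfig(
        chrom_names=names, chrom_sizes_mb=sizes, n_markers=960, n_accessions=1800
    )
    return replace(cfg, **overrides)


@dataclass
class SimTruth:
    """Ground truth of a simulated population, for validating the analyses."""

    site_meta: pd.DataFrame
    station: np.ndarray  # per-accession station code
    true_dosages: np.ndarray  # pre-missing-injection dosage matrix
    catalog: pd.DataFrame  # candidate-catalog view of the panel
    station_freq: np.ndarray | None = None  # stations x markers founder allele freqs
    qtl: dict = field(default_factory=dict)  # trait -> site indices
    effects: dict = field(default_factory=dict)  # trait -> effect sizes
    breeding_values: dict = field(default_factory=dict)  # trait -> g = M a
    realized_h2: dict = field(default_factory=dict)


def _allocate_markers(config: SimConfig) -> np.ndarray:
    """Markers per chromosome, proportional to size (largest remainder)."""
    sizes = np.asarray(config.chrom_sizes_mb, dtype=float)
    quota = config.n_markers * sizes / sizes.sum()
    n = np.floor(quota).astype(int)
    n = np.maximum(n, 2)  # spacing needs two terminal markers
    rest = config.n_markers - n.sum()
    if rest < 0:
        raise ValueError("n_markers infeasible for the chromosome count")
    order = np.argsort(quota - np.floor(quota))[::-1]
    for i in range(rest):
        n[order[i % len(n)]] += 1
    return n


def simulate_markers(config: SimConfig, rng: np.random.Generator | None = None,
                     n_markers: int | None = None) -> pd.DataFrame:
    """Draw a marker catalog: near-uniform jittered positions plus QC fields.

    Positions tile each chromosome at even spacing with uniform jitter of
    ``position_jitter`` x spacing (jitter 0 gives exactly uniform spacing).
    Catalog QC fields are drawn independently: missing rates Beta(1.2, 10),
    mapping classes 1-5 (categorical, most candidates clean), MAF from a
    folded Beta ancestral-frequency draw, and secondary-polymorphism counts
    Poisson(``extra_poly_mean``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_markers is not None:
        config = replace(config, n_markers=n_markers)
    per_chrom = _allocate_markers(config)

    rows = []
    for chrom, size_mb, n in zip(config.chrom_names, config.chrom_sizes_mb, per_chrom):
        spacing = size_mb / n
        centers = (np.arange(n) + 0.5) * spacing
        jitter = config.position_jitter * spacing * rng.uniform(-0.5, 0.5, size=n)
        pos_mb = np.sort(np.clip(centers + jitter, 0.0, size_mb))
        for j, p in enumerate(pos_mb):
            rows.append((f"{chrom}_M{j + 1:04d}", chrom, int(round(p * 1e6))))
    catalog = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp"])

    m = len(catalog)
    a, b = config.ancestral_beta
    p = np.clip(rng.beta(a, b, size=m), 0.02, 0.98)
    catalog["missing_rate"] = np.clip(rng.beta(1.2, 10.0, size=m), 0.0, 1.0)
    catalog["maf"] = np.minimum(p, 1 - p)
    catalog["map_class"] = rng.choice(
        [1, 2, 3, 4, 5], size=m, p=[0.45, 0.20, 0.15, 0.12, 0.08]
    )
    catalog["n_extra_polymorphisms"] = rng.poisson(config.extra_poly_mean, size=m)
    catalog.attrs["ancestral_freq"] = p
    return catalog


def _recomb_prob(site_meta: pd.DataFrame, cm_per_mb: float) -> np.ndarray:
    """Per-interval switch probabilities under the Haldane map function.

    The first marker of each chromosome gets probability 0.5, which makes the
    starting haplotype uniform and independent between chromosomes.
    """
    pos_mb = site_meta["pos_bp"].to_numpy() / 1e6
    chrom = site_meta["chrom"].to_numpy()
    d_morgan = np.diff(pos_mb, prepend=pos_mb[0]) * cm_per_mb / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * np.clip(d_morgan, 0.0, None)))
    new_chrom = np.r_[True, chrom[1:] != chrom[:-1]]
    r[new_chrom] = 0.5
    return r


def _gametes(hap_a: np.ndarray, hap_b: np.ndarray, r: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per individual (rows), vectorized."""
    switch = rng.random(hap_a.shape) < r[None, :]
    state = np.cumsum(switch, axis=1) % 2
    return np.where(state == 0, hap_a, hap_b)


def simulate_population(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate genotypes of a station-structured inbred population.

    Station founder allele frequencies follow the Balding-Nichols model
    around a common ancestral frequency: p_station ~ Beta(p(1-F)/F,
    (1-p)(1-F)/F).  Founders are fully inbred; each accession is an F1 of two
    distinct same-station founders selfed for ``selfing_generations`` rounds
    with Haldane crossovers.  Missing calls are finally injected completely at
    random at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    catalog = simulate_markers(config, rng=rng)
    site_meta = catalog[["marker_id", "chrom", "pos_bp"]].copy()
    site_meta["ref"] = "A"
    site_meta["alt"] = "G"
    m = len(site_meta)
    p0 = catalog.attrs["ancestral_freq"]

    stations = np.array(config.station_codes[: config.n_stations])
    F = config.fst
    if F > 0:
        shape1 = p0 * (1 - F) / F
        shape2 = (1 - p0) * (1 - F) / F
        p_station = np.vstack(
            [rng.beta(shape1, shape2) for _ in range(config.n_stations)]
        )
    else:
        p_station = np.tile(p0, (config.n_stations, 1))

    # inbred founders: one haplotype each, doubled
    nf = config.founders_per_station
    founder_haps = np.stack(
        [(rng.random((nf, m)) < p_station[s][None, :]).astype(np.int8)
         for s in range(config.n_stations)]
    )  # stations x founders x markers

    n = config.n_accessions
    station_idx = rng.integers(0, config.n_stations, size=n)
    p1 = rng.integers(0, nf, size=n)
    shift = rng.integers(1, nf, size=n)
    p2 = (p1 + shift) % nf  # distinct second parent
    hap_a = founder_haps[station_idx, p1]
    hap_b = founder_haps[station_idx, p2]

    r = _recomb_prob(site_meta, config.recomb_rate_cM_per_mb)
    for _ in range(config.selfing_generations):
        g1 = _gametes(hap_a, hap_b, r, rng)
        g2 = _gametes(hap_a, hap_b, r, rng)
        hap_a, hap_b = g1, g2

    true_dosages = (hap_a + hap_b).astype(float)

    dosages = true_dosages.copy()
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = np.nan

    years = np.array(config.years)[rng.integers(0, len(config.years), size=n)]
    accession_meta = pd.DataFrame(
        {
            "accession_id": [f"ACC{i + 1:05d}" for i in range(n)],
            "station": stations[station_idx],
            "year": years,
        }
    )
    gm = GenotypeMatrix(dosages, site_meta, accession_meta)

    # refresh catalog MAF with the frequencies realized in the population
    freq = true_dosages.mean(axis=0) / 2.0
    catalog = catalog.copy()
    catalog["maf"] = np.minimum(freq, 1 - freq)

    truth = SimTruth(
        site_meta=site_meta,
        station=stations[station_idx],
        true_dosages=true_dosages,
        catalog=catalog,
        station_freq=p_station,
    )
    return gm, truth


def simulate_phenotypes(truth: SimTruth, gm: GenotypeMatrix, config: SimConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Polygenic phenotypes with station/year location and scale shifts.

    Per trait: QTL are drawn among polymorphic panel sites with N(0, 1)
    effects; the breeding value is g = M a on the true (complete) dosages;
    residual variance is set so var(g) / (var(g) + var(e)) matches the target
    heritability; each (station, year) combination adds a location shift
    (station- and year-level normal effects) and inflates the residual scale
    by a lognormal factor (sd ``group_scale_sd`` on the log scale).  The
    realized heritability var(g) / (var(g) + var(e_actual)) is recorded in
    ``truth.realized_h2``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = gm.n_accessions
    meta = gm.accession_meta
    stations = np.array(config.station_codes[: config.n_stations])
    rows = []
    for spec in config.traits:
        poly = np.flatnonzero(truth.true_dosages.var(axis=0) > 0)
        if spec.n_qtl > len(poly):
            raise ValueError(f"trait {spec.name}: {spec.n_qtl} QTL exceed polymorphic sites")
        qtl = rng.choice(poly, size=spec.n_qtl, replace=False) if spec.n_qtl else np.array([], int)
        a = rng.normal(0.0, 1.0, size=spec.n_qtl)
        g = truth.true_dosages[:, qtl] @ a if spec.n_qtl else np.zeros(n)
        if spec.h2 > 0 and g.var() > 0:
            g_used = g
            var_g = g.var()
            sigma_e = np.sqrt(var_g * (1 - spec.h2) / spec.h2) if spec.h2 < 1 else 0.0
        else:
            # h2 = 0: the trait carries no genetic signal, but the drawn
            # breeding values stay in the truth record for null checks
            g_used = np.zeros(n)
            var_g = 0.0
            sigma_e = 1.0

        base_sd = np.sqrt(var_g + sigma_e**2) or 1.0
        st_loc = dict(
            zip(stations, rng.normal(0, spec.station_effect_sd * base_sd, len(stations)))
        )
        combos = [(s, y) for s in stations for y in config.years]
        yr_loc = {c: rng.normal(0, spec.year_effect_sd * base_sd) for c in combos}
        scale = {c: np.exp(rng.normal(0, config.group_scale_sd)) for c in combos}

        keys = list(zip(meta["station"], meta["year"]))
        e = rng.normal(0, 1, size=n) * sigma_e * np.array([scale[k] for k in keys])
        y = (
            g_used
            + np.array([st_loc[s] for s in meta["station"]])
            + np.array([yr_loc[k] for k in keys])
            + e
        )
        var_e = e.var()
        truth.qtl[spec.name] = qtl
        truth.effects[spec.name] = a
        truth.breeding_values[spec.name] = g
        truth.realized_h2[spec.name] = float(var_g / (var_g + var_e)) if (var_g + var_e) else 0.0
        for i in range(n):
            rows.append(
                (meta["accession_id"].iloc[i], meta["station"].iloc[i],
                 int(meta["year"].iloc[i]), spec.name, float(y[i]))
            )
    return pd.DataFrame(rows, columns=["accession_id", "station", "year", "trait", "value"])


# ---------------------------------------------------------------------------
# fixture output

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (GT only) for a genotype matrix."""
    meta = gm.site_meta
    samples = gm.accession_meta["accession_id"].tolist()
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=corepanel-simulator\n")
        for chrom, grp in meta.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos_bp'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(gm.n_sites):
            r = meta.iloc[j]
            gts = "\t".join(
                _GT.get(d, "./.") if not np.isnan(d) else "./."
                for d in gm.dosages[:, j]
            )
            fh.write(
                f"{r['chrom']}\t{int(r['pos_bp'])}\t{r['marker_id']}\t{r['ref']}\t"
                f"{r['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_fixture(gm: GenotypeMatrix, pheno: pd.DataFrame, catalog: pd.DataFrame,
                  config: SimConfig, truth: SimTruth, outdir) -> dict:
    """Write a complete offline test fixture; returns the file paths.

    Emits a VCF with the genotypes, tab-separated phenotype / catalog /
    chromosome-size tables, accession metadata, and a JSON truth file with the
    realized heritabilities and planted QTL positions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "catalog": outdir / "catalog.tsv",
        "chrom_sizes": outdir / "chrom_sizes.tsv",
        "accessions": outdir / "accessions.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(gm, paths["vcf"])
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False)
    catalog.to_csv(paths["catalog"], sep="\t", index=False)
    pd.DataFrame(
        {"chrom": config.chrom_names, "size_mb": config.chrom_sizes_mb}
    ).to_csv(paths["chrom_sizes"], sep="\t", index=False)
    gm.accession_meta.to_csv(paths["accessions"], sep="\t", index=False)
    truth_doc = {
        "seed": config.seed,
        "n_accessions": gm.n_accessions,
        "n_markers": gm.n_sites,
        "realized_h2": truth.realized_h2,
        "qtl": {t: truth.site_meta["marker_id"].iloc[idx].tolist()
                for t, idx in truth.qtl.items()},
        "n_secondary_polymorphic": int((catalog["n_extra_polymorphisms"] > 0).sum()),
    }
    with open(paths["truth"], "wt") as fh:
        json.dump(truth_doc, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
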