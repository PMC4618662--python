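"""Synthetic transdifferentiation cohort with planted ground truth.

Generates a complete desk-scale input set emulating the statistical
structure of an induced pre-B -> macrophage ChIP-seq/expression time
course: per-time-point TF peak calls (hour-scale and early minute-scale
series), Gaussian-peak histone-mark/P300 coverage tracks over Poisson
background, a gene annotation, expression tables with planted fold
changes, per-cell-type peak sets realizing lineage activity and occupancy
fractions, MNase fragment sets with phased vs dense nucleosome structure,
and a truth table recording every planted label.

Design notes
------------
* The genome is laid out in fixed-size "units", each holding one gene TSS
  and one enhancer at a jittered distal offset, dimensioned so that the
  enhancer's designated gene is provably its nearest TSS.  Genes without a
  paired enhancer live in per-chromosome "desert" segments separated from
  the enhancer units by a 500 kb buffer, which makes the 100-kb window
  association fraction identifiable.
* Planted fractions are realized by exact counts (round(f*n) items get the
  property), not Bernoulli draws, so recovery tolerances are dominated by
  pipeline noise only.  Lineage activity/occupancy selections are
  stratified over promoter states within each class, keeping the planted
  fraction sharp on any class subset.
* Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeModel

UNIT_LENGTH = 24_000
UNIT_TSS_OFFSET = 2_000
GENE_BODY = 2_000
DESERT_BUFFER = 500_000
DESERT_GENE_SPACING = 2_500
BG_BIN = 1_000           # bedGraph background run length
PEAK_GRID = 25           # bedGraph peak bin width
PEAK_EXTENT = 750        # peaks written over center +/- PEAK_EXTENT
FRAGMENT_LENGTH = 147
TRANSIENT_SLOT_STEP = 1_500

MARKS = ("H3K4Me1", "H3K27Ac", "P300", "H3K4Me3", "H3K27Me3")
ACTIVE_ENH_MARKS = ("H3K4Me1", "H3K27Ac", "P300")

#: Per cell type: (fraction of pre-existing, fraction of de novo) enhancers
#: decorated with active marks.  Values printed in the source study are used
#: verbatim; intermediate nodes interpolate its narrative ranges.
DEFAULT_LINEAGE_ACTIVITY: dict[str, tuple[float, float]] = {
    "LT-HSC": (0.58, 0.07),
    "MPP": (0.60, 0.14),
    "CMP": (0.65, 0.25),
    "GMP": (0.68, 0.28),
    "Gn": (0.66, 0.40),
    "MPhi": (0.74, 0.40),
    "MEP": (0.30, 0.02),
    "Ery": (0.30, 0.02),
    "CLP": (0.62, 0.03),
    "B": (0.60, 0.02),
    "T": (0.30, 0.02),
}

#: Per cell type: (pre-existing, de novo) fractions bound by C/EBPα.
DEFAULT_OCCUPANCY: dict[str, tuple[float, float]] = {
    "LSK": (0.05, 0.05),
    "GMP": (0.80, 0.80),
    "MPhi": (0.80, 0.80),
}

MYELOID_TYPES = ("GMP", "Gn", "MPhi")


class ScenarioError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Generator parameters; defaults are the study's printed quantities."""

    n_chroms: int = 4
    chrom_length: int = 10_000_000
    n_pre_existing: int = 800
    n_de_novo: int = 600
    n_genes: int = 3_000
    time_points_hpi: tuple[int, ...] = (0, 3, 12, 24, 48)
    early_time_points_min: tuple[int, ...] = (10, 30, 60)
    frac_cebpa_first_de_novo: float = 0.74
    frac_prebound_pu1: float = 0.40
    promoter_state_mix_pre_existing: tuple[float, float, float] = (0.73, 0.07, 0.20)
    promoter_state_mix_de_novo: tuple[float, float, float] = (0.36, 0.44, 0.20)
    frac_upregulated_within_100kb: float = 0.70
    fold_change_pre_existing: float = 4.0
    fold_change_de_novo: float = 9.0
    baseline_expression_pre_existing: float = 200.0
    baseline_expression_de_novo: float = 30.0
    frac_ebf1_pre_existing: float = 0.50
    transient_ratio: float = 4.0
    min_tss_enhancer_distance: int = 10_000
    lineage_activity: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LINEAGE_ACTIVITY)
    )
    occupancy: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPANCY)
    )
    background_rate: float = 0.02  # per-bp Poisson rate of mark tracks
    peak_height: float = 50.0      # Gaussian mode, in multiples of background
    peak_width: int = 1_000        # TF peak interval width; mark sd = width/4
    expression_sigma: float = 0.15  # log-normal noise on expression values
    seed: int = 1

    def validate(self) -> None:
        fracs = [
            self.frac_cebpa_first_de_novo,
            self.frac_prebound_pu1,
            self.frac_upregulated_within_100kb,
            self.frac_ebf1_pre_existing,
            *[f for pair in self.lineage_activity.values() for f in pair],
            *[f for pair in self.occupancy.values() for f in pair],
        ]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ScenarioError("all fractions must lie in [0, 1]")
        for mix in (self.promoter_state_mix_pre_existing, self.promoter_state_mix_de_novo):
            if any(f < 0 for f in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise ScenarioError("promoter-state proportions must sum to 1")
        if list(self.time_points_hpi) != sorted(set(self.time_points_hpi)):
            raise ScenarioError("time points must be strictly increasing")
        if list(self.early_time_points_min) != sorted(set(self.early_time_points_min)):
            raise ScenarioError("early time points must be strictly increasing")
        if self.n_genes < self.n_pre_existing + self.n_de_novo:
            raise ScenarioError("need at least one gene per enhancer")

    @property
    def n_enhancers(self) -> int:
        return self.n_pre_existing + self.n_de_novo

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        data["time_points_hpi"] = list(self.time_points_hpi)
        data["early_time_points_min"] = list(self.early_time_points_min)
        data["promoter_state_mix_pre_existing"] = list(self.promoter_state_mix_pre_existing)
        data["promoter_state_mix_de_novo"] = list(self.promoter_state_mix_de_novo)
        data["lineage_activity"] = {k: list(v) for k, v in self.lineage_activity.items()}
        data["occupancy"] = {k: list(v) for k, v in self.occupancy.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("time_points_hpi", "early_time_points_min",
                    "promoter_state_mix_pre_existing", "promoter_state_mix_de_novo"):
            if key in data:
                data[key] = tuple(data[key])
        for key in ("lineage_activity", "occupancy"):
            if key in data:
                data[key] = {k: tuple(v) for k, v in data[key].items()}
        return cls(**data)


def paper_default_config(seed: int = 1) -> ScenarioConfig:
    """The default scenario: planted parameters equal the study's printed
    headline quantities (binding order 74%, promoter mixes 73/7/20 and
    36/44/20, 40% PU.1 pre-binding, 70% within 100 kb, 4x/9x folds,
    lineage/occupancy fractions)."""
    cfg = ScenarioConfig(seed=seed)
    cfg.validate()
    return cfg


@dataclass
class TruthTable:
    """Planted per-enhancer and per-gene labels for recovery testing."""

    enhancers: pd.DataFrame
    genes: pd.DataFrame

    @classmethod
    def load(cls, out_dir: str | Path) -> "TruthTable":
        out_dir = Path(out_dir)
        enh = pd.read_csv(out_dir / "truth_enhancers.tsv", sep="\t")
        genes = pd.read_csv(out_dir / "truth_genes.tsv", sep="\t")
        return cls(enh, genes)


@dataclass
class SyntheticDataset:
    """Path book-keeping for one generated scenario."""

    out_dir: Path
    config: ScenarioConfig
    genome: GenomeModel

    def path(self, name: str) -> Path:
        return self.out_dir / name

    def tf_bed(self, factor: str, series: str, tp: int) -> Path:
        return self.out_dir / f"{factor}_{series}_{tp}.bed"

    def mark_track(self, mark: str, tp: int) -> Path:
        return self.out_dir / f"{mark.lower()}_hpi_{tp}.bg"

    def celltype_bed(self, what: str, cell_type: str) -> Path:
        return self.out_dir / f"{what}_{cell_type}.bed"

    def mnase_bed(self, condition: str) -> Path:
        return self.out_dir / f"mnase_{condition}.bed"

    @property
    def genes_bed(self) -> Path:
        return self.out_dir / "genes.bed"

    @property
    def expression_timecourse(self) -> Path:
        return self.out_dir / "expression_timecourse.tsv"

    @property
    def expression_celltypes(self) -> Path:
        return self.out_dir / "expression_celltypes.tsv"


def exact_counts(fracs: Sequence[float], n: int) -> list[int]:
    """Integer counts summing to n, apportioned by largest remainder."""
    raw = [f * n for f in fracs]
    base = [int(math.floor(x)) for x in raw]
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[: n - sum(base)]:
        base[i] += 1
    return base


def _bed_line(chrom: str, start: int, end: int, name: str, score: float, strand: str) -> str:
    return f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n"


def _write_bed_rows(path: Path, rows: list[tuple[str, int, int, str, float, str]]) -> None:
    rows = sorted(rows, key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write(_bed_line(*r))


def _gaussian_peak_rows(chrom: str, center: int, amplitude: float, sd: float):
    """Run-length bedGraph rows for one Gaussian-shaped peak."""
    edges = np.arange(-PEAK_EXTENT, PEAK_EXTENT + PEAK_GRID, PEAK_GRID)
    mids = (edges[:-1] + edges[1:]) / 2.0
    vals = amplitude * np.exp(-(mids**2) / (2.0 * sd * sd))
    starts = center + edges[:-1]
    ends = center + edges[1:]
    return starts, ends, vals


def _write_track(
    path: Path,
    genome: GenomeModel,
    rng: np.random.Generator,
    background_rate: float,
    peaks: list[tuple[str, int, float]],
    sd: float,
) -> None:
    """Background (Poisson per kb, run-length) plus additive Gaussian peaks.

    Overlapping records are additive by the bedGraph reader contract.
    """
    frames = []
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        n_bins = length // BG_BIN
        counts = rng.poisson(background_rate * BG_BIN, n_bins)
        keep = counts > 0
        starts = (np.arange(n_bins) * BG_BIN)[keep]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + BG_BIN,
                    "value": counts[keep] / BG_BIN,
                }
            )
        )
    for chrom, center, amplitude in peaks:
        if amplitude <= 0:
            continue
        s, e, v = _gaussian_peak_rows(chrom, center, amplitude, sd)
        frames.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e, "value": v}))
    df = pd.concat(frames, ignore_index=True)
    df.sort_values(["chrom", "start"], kind="stable", inplace=True)
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def _pick(rng: np.random.Generator, pool: np.ndarray, count: int) -> np.ndarray:
    """Deterministic sample of ``count`` items without replacement."""
    count = min(count, pool.size)
    return rng.choice(pool, size=count, replace=False)


def generate_scenario(
    config: ScenarioConfig, out_dir: str | Path
) -> tuple[SyntheticDataset, TruthTable]:
    """Write the full synthetic dataset and its truth table to ``out_dir``."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genome = GenomeModel(
        tuple(f"chr{i + 1}" for i in range(config.n_chroms)),
        tuple(config.chrom_length for _ in range(config.n_chroms)),
    )

    n_units = config.n_enhancers
    d_lo = config.min_tss_enhancer_distance + 200
    d_hi = UNIT_LENGTH // 2 - 200
    if d_lo >= d_hi:
        raise ScenarioError("min_tss_enhancer_distance too large for unit layout")

    # --- unit layout ------------------------------------------------------
    units_per_chrom = [n_units // config.n_chroms] * config.n_chroms
    for i in range(n_units % config.n_chroms):
        units_per_chrom[i] += 1

    n_desert = config.n_genes - n_units
    desert_per_chrom = [n_desert // config.n_chroms] * config.n_chroms
    for i in range(n_desert % config.n_chroms):
        desert_per_chrom[i] += 1

    for ci in range(config.n_chroms):
        need = (
            units_per_chrom[ci] * UNIT_LENGTH
            + DESERT_BUFFER
            + desert_per_chrom[ci] * DESERT_GENE_SPACING
            + UNIT_TSS_OFFSET
            + GENE_BODY
        )
        if need > config.chrom_length:
            raise ScenarioError("genome too small for the requested counts")

    # per-unit coordinates
    unit_chrom: list[str] = []
    unit_tss: list[int] = []
    enh_mid: list[int] = []
    for ci in range(config.n_chroms):
        chrom = genome.chrom_names[ci]
        for u in range(units_per_chrom[ci]):
            start = u * UNIT_LENGTH
            tss = start + UNIT_TSS_OFFSET
            d = int(rng.integers(d_lo, d_hi + 1))
            unit_chrom.append(chrom)
            unit_tss.append(tss)
            enh_mid.append(tss + d)

    half_w = config.peak_width // 2
    enh_start = np.array(enh_mid) - half_w
    enh_end = np.array(enh_mid) + (config.peak_width - half_w)

    # --- planted labels ---------------------------------------------------
    classes = np.array(
        ["pre_existing"] * config.n_pre_existing + ["de_novo"] * config.n_de_novo
    )
    classes = classes[rng.permutation(n_units)]
    pre_idx = np.flatnonzero(classes == "pre_existing")
    dn_idx = np.flatnonzero(classes == "de_novo")

    promoter_state = np.empty(n_units, dtype=object)
    promoter_substate = np.empty(n_units, dtype=object)  # inactive: k27me3|none
    for idx, mix in (
        (pre_idx, config.promoter_state_mix_pre_existing),
        (dn_idx, config.promoter_state_mix_de_novo),
    ):
        counts = exact_counts(mix, idx.size)
        labels = (
            ["active"] * counts[0] + ["inactive"] * counts[1] + ["bivalent"] * counts[2]
        )
        perm = rng.permutation(idx.size)
        for k, lab in zip(perm, labels):
            promoter_state[idx[k]] = lab
    for i in range(n_units):
        if promoter_state[i] == "inactive":
            promoter_substate[i] = "k27me3" if rng.random() < 0.5 else "none"
        else:
            promoter_substate[i] = ""

    n_prebound = int(round(config.frac_prebound_pu1 * n_units))
    prebound = np.zeros(n_units, dtype=bool)
    pool = pre_idx if n_prebound <= pre_idx.size else np.arange(n_units)
    prebound[_pick(rng, pool, n_prebound)] = True

    ebf1 = np.zeros(n_units, dtype=bool)
    ebf1[_pick(rng, pre_idx, int(round(config.frac_ebf1_pre_existing * pre_idx.size)))] = True

    # binding order on de novo sites
    early = list(config.early_time_points_min)
    order_label = np.empty(n_units, dtype=object)
    order_label[:] = ""
    # stratified over promoter states so the planted fraction stays sharp on
    # any promoter-defined subset of the de novo class
    for ps in ("active", "inactive", "bivalent"):
        stratum = dn_idx[promoter_state[dn_idx] == ps]
        n_a = int(round(config.frac_cebpa_first_de_novo * stratum.size))
        n_rest = stratum.size - n_a
        n_sim = n_rest // 2
        dn_orders = (
            ["a_first"] * n_a
            + ["simultaneous"] * n_sim
            + ["b_first"] * (n_rest - n_sim)
        )
        perm = rng.permutation(stratum.size)
        for k, lab in zip(perm, dn_orders):
            order_label[stratum[k]] = lab

    ordered_pairs = [(a, b) for a in early for b in early if a < b]
    cebpa_min = np.zeros(n_units, dtype=int)
    pu1_min = np.zeros(n_units, dtype=int)
    for i in range(n_units):
        if classes[i] == "pre_existing":
            cebpa_min[i] = early[int(rng.integers(len(early)))]
            # PU.1 pre-bound sites carry PU.1 from t=0; the rest acquire it
            # during the early series
            pu1_min[i] = 0 if prebound[i] else early[int(rng.integers(len(early)))]
        else:
            lab = order_label[i]
            if lab == "simultaneous":
                t = early[int(rng.integers(len(early)))]
                cebpa_min[i], pu1_min[i] = t, t
            else:
                a, b = ordered_pairs[int(rng.integers(len(ordered_pairs)))]
                if lab == "a_first":
                    cebpa_min[i], pu1_min[i] = a, b
                else:
                    cebpa_min[i], pu1_min[i] = b, a

    # lineage activity / occupancy, stratified over promoter states so the
    # planted fraction holds on any promoter-defined class subset
    strata = {
        (cls, ps): np.flatnonzero((classes == cls) & (promoter_state == ps))
        for cls in ("pre_existing", "de_novo")
        for ps in ("active", "inactive", "bivalent")
    }

    def stratified_select(frac_by_class: dict[str, float]) -> np.ndarray:
        sel = np.zeros(n_units, dtype=bool)
        for (cls, _), members in strata.items():
            if members.size == 0:
                continue
            sel[_pick(rng, members, int(round(frac_by_class[cls] * members.size)))] = True
        return sel

    activity_sel = {
        ct: stratified_select({"pre_existing": fp, "de_novo": fd})
        for ct, (fp, fd) in config.lineage_activity.items()
    }
    k4me1_sel = {
        ct: stratified_select({"pre_existing": fp, "de_novo": fd})
        for ct, (fp, fd) in config.lineage_activity.items()
    }
    occupancy_sel = {
        ct: stratified_select({"pre_existing": fp, "de_novo": fd})
        for ct, (fp, fd) in config.occupancy.items()
    }

    # --- genes ------------------------------------------------------------
    gene_ids = [f"gene{(i + 1):05d}" for i in range(config.n_genes)]
    gene_chrom: list[str] = list(unit_chrom)
    gene_tss: list[int] = list(unit_tss)
    desert_first = []
    for ci in range(config.n_chroms):
        desert_first.append(units_per_chrom[ci] * UNIT_LENGTH + DESERT_BUFFER)
    for ci in range(config.n_chroms):
        chrom = genome.chrom_names[ci]
        for k in range(desert_per_chrom[ci]):
            gene_chrom.append(chrom)
            gene_tss.append(desert_first[ci] + UNIT_TSS_OFFSET + k * DESERT_GENE_SPACING)
    gene_strand = np.where(rng.random(config.n_genes) < 0.5, "+", "-")

    # regulation labels: every enhancer-designated gene is upregulated with
    # the class fold; "far" upregulated genes live in the deserts
    n_up_total = int(round(n_units / config.frac_upregulated_within_100kb)) if (
        config.frac_upregulated_within_100kb > 0
    ) else n_units
    n_far_up = n_up_total - n_units
    if n_far_up > n_desert:
        raise ScenarioError("genome too small: not enough desert genes for the "
                            "requested upregulated-gene placement fraction")
    desert_idx = np.arange(n_units, config.n_genes)
    regulation = np.empty(config.n_genes, dtype=object)
    fold = np.ones(config.n_genes)
    baseline = np.full(config.n_genes, 100.0)
    regulation[:n_units] = "up"
    for i in range(n_units):
        if classes[i] == "pre_existing":
            fold[i] = config.fold_change_pre_existing
            baseline[i] = config.baseline_expression_pre_existing
        else:
            fold[i] = config.fold_change_de_novo
            baseline[i] = config.baseline_expression_de_novo
    desert_perm = desert_idx[rng.permutation(desert_idx.size)]
    far_up = desert_perm[:n_far_up]
    rest = desert_perm[n_far_up:]
    n_down = rest.size // 2
    down = rest[:n_down]
    unchanged = rest[n_down:]
    regulation[far_up] = "up"
    fold[far_up] = rng.uniform(2.5, 6.0, far_up.size)
    baseline[far_up] = 50.0
    regulation[down] = "down"
    fold[down] = 0.25
    baseline[down] = 200.0
    regulation[unchanged] = "unchanged"
    fold[unchanged] = 1.0

    gene_rows = []
    for i in range(config.n_genes):
        tss = gene_tss[i]
        if gene_strand[i] == "+":
            s, e = tss, tss + GENE_BODY
        else:
            s, e = tss - GENE_BODY + 1, tss + 1
        gene_rows.append((gene_chrom[i], s, e, gene_ids[i], 0.0, str(gene_strand[i])))
    ds = SyntheticDataset(out_dir, config, genome)
    _write_bed_rows(ds.genes_bed, gene_rows)

    # --- transient TF sites ----------------------------------------------
    post_times = [t for t in config.time_points_hpi if t != config.time_points_hpi[0]]
    non_terminal = post_times[:-1]
    n_transient = int(round(config.transient_ratio * n_units)) if non_terminal else 0
    slots_per_unit = math.ceil(n_transient / n_units) if n_transient else 0
    slot_base = UNIT_TSS_OFFSET + d_hi + half_w + 500
    max_mid = UNIT_LENGTH - half_w - 200
    if slots_per_unit and slot_base + 750 + (slots_per_unit - 1) * TRANSIENT_SLOT_STEP > max_mid:
        raise ScenarioError("genome too small: transient_ratio exceeds unit capacity")
    transient: list[tuple[str, int, int, int]] = []  # chrom, mid, first_t, last_t
    t_count = 0
    for u in range(n_units):
        u_start = (unit_tss[u] - UNIT_TSS_OFFSET)
        for k in range(slots_per_unit):
            if t_count >= n_transient:
                break
            mid = u_start + slot_base + 750 + k * TRANSIENT_SLOT_STEP
            fi = int(rng.integers(len(non_terminal)))
            li = int(rng.integers(fi, len(non_terminal)))
            transient.append((unit_chrom[u], mid, non_terminal[fi], non_terminal[li]))
            t_count += 1

    # --- TF peak BEDs -----------------------------------------------------
    def enh_row(i: int, score: float = 1.0) -> tuple[str, int, int, str, float, str]:
        return (
            unit_chrom[i],
            int(enh_start[i]),
            int(enh_end[i]),
            f"enh{i + 1:05d}",
            score,
            ".",
        )

    t0 = config.time_points_hpi[0]
    for t in config.time_points_hpi:
        cebpa_rows, pu1_rows, cebpb_rows = [], [], []
        if t != t0:
            cebpa_rows = [enh_row(i) for i in range(n_units)]
            pu1_rows = [enh_row(i) for i in range(n_units)]
            cebpb_rows = [enh_row(i) for i in range(n_units)]
            for j, (chrom, mid, ft, lt) in enumerate(transient):
                if ft <= t <= lt:
                    cebpa_rows.append(
                        (chrom, mid - half_w, mid + (config.peak_width - half_w),
                         f"trans{j + 1:05d}", 1.0, ".")
                    )
        else:
            pu1_rows = [enh_row(i) for i in np.flatnonzero(prebound)]
        _write_bed_rows(ds.tf_bed("cebpa", "hpi", t), cebpa_rows)
        _write_bed_rows(ds.tf_bed("pu1", "hpi", t), pu1_rows)
        _write_bed_rows(ds.tf_bed("cebpb", "hpi", t), cebpb_rows)

    for m in config.early_time_points_min:
        cebpa_rows = [enh_row(i) for i in range(n_units) if cebpa_min[i] <= m]
        pu1_rows = [enh_row(i) for i in range(n_units) if pu1_min[i] <= m]
        _write_bed_rows(ds.tf_bed("cebpa", "min", m), cebpa_rows)
        _write_bed_rows(ds.tf_bed("pu1", "min", m), pu1_rows)

    _write_bed_rows(
        ds.path("ebf1_preB.bed"), [enh_row(i) for i in np.flatnonzero(ebf1)]
    )

    # --- mark coverage tracks --------------------------------------------
    terminal = config.time_points_hpi[-1]
    sd = config.peak_width / 4.0
    amp = config.peak_height * config.background_rate

    def enhancer_multiplier(mark: str, cls: str, t: int) -> float:
        if cls == "pre_existing":
            if mark in ACTIVE_ENH_MARKS:
                return 1.0 + 0.5 * t / terminal  # hyper-activation on induction
            return 0.0
        if mark in ACTIVE_ENH_MARKS:
            return 0.0 if t == t0 else min(t / 24.0, 1.0)
        return max(1.0 - t / 24.0, 0.0)  # H3K27Me3 decay after pioneer binding

    for t in config.time_points_hpi:
        for mark in MARKS:
            peaks: list[tuple[str, int, float]] = []
            if mark in ACTIVE_ENH_MARKS or mark == "H3K27Me3":
                for i in range(n_units):
                    mult = enhancer_multiplier(mark, classes[i], t)
                    if mult > 0:
                        peaks.append((unit_chrom[i], int(enh_mid[i]), amp * mult))
            if mark == "H3K4Me3":
                for i in range(n_units):
                    if promoter_state[i] in ("active", "bivalent"):
                        peaks.append((gene_chrom[i], gene_tss[i], amp))
                for i in range(n_units, config.n_genes):
                    peaks.append((gene_chrom[i], gene_tss[i], amp))
            if mark == "H3K27Me3":
                for i in range(n_units):
                    if promoter_state[i] == "bivalent" or promoter_substate[i] == "k27me3":
                        peaks.append((gene_chrom[i], gene_tss[i], amp))
            _write_track(
                ds.mark_track(mark, t), genome, rng, config.background_rate, peaks, sd
            )

    # --- expression -------------------------------------------------------
    times = list(config.time_points_hpi)
    sig = config.expression_sigma
    expr = np.empty((config.n_genes, len(times)))
    for j, t in enumerate(times):
        kinetic = fold ** (t / terminal)
        noise = np.exp(rng.normal(0.0, sig, config.n_genes))
        expr[:, j] = baseline * kinetic * noise
    pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"),
                 columns=[str(t) for t in times]).round(4).to_csv(
        ds.expression_timecourse, sep="\t"
    )

    cell_types = list(config.lineage_activity.keys())
    expr_ct = np.empty((config.n_genes, len(cell_types)))
    for j, ct in enumerate(cell_types):
        level = baseline.copy()
        if ct in MYELOID_TYPES:
            level[:n_units] = baseline[:n_units] * fold[:n_units]
        noise = np.exp(rng.normal(0.0, sig, config.n_genes))
        expr_ct[:, j] = level * noise
    pd.DataFrame(expr_ct, index=pd.Index(gene_ids, name="gene_id"),
                 columns=cell_types).round(4).to_csv(ds.expression_celltypes, sep="\t")

    # --- per-cell-type peak BEDs (lineage activity and occupancy) ---------
    def jittered_rows(sel: np.ndarray) -> list[tuple[str, int, int, str, float, str]]:
        rows = []
        for i in np.flatnonzero(sel):
            shift = int(rng.integers(-300, 301))
            mid = int(enh_mid[i]) + shift
            rows.append(
                (unit_chrom[i], mid - half_w, mid + (config.peak_width - half_w),
                 f"enh{i + 1:05d}", 1.0, ".")
            )
        return rows

    for ct in cell_types:
        _write_bed_rows(ds.celltype_bed("k27ac", ct), jittered_rows(activity_sel[ct]))
        _write_bed_rows(ds.celltype_bed("k4me1", ct), jittered_rows(k4me1_sel[ct]))
    for ct in config.occupancy:
        _write_bed_rows(ds.celltype_bed("cebpa", ct), jittered_rows(occupancy_sel[ct]))

    # --- MNase fragments --------------------------------------------------
    def mnase_rows(spec: list[tuple[np.ndarray, list[str], int, float, int]]):
        rows = []
        for mids, chroms, n_phased, phase_sd, n_uniform in spec:
            k = 0
            for mid, chrom in zip(mids, chroms):
                centers = np.concatenate([
                    rng.normal(mid - 150, phase_sd, n_phased),
                    rng.normal(mid + 150, phase_sd, n_phased),
                    rng.uniform(mid - 1000, mid + 1000, 30 - 2 * n_phased),
                ]).astype(int)
                for c in centers:
                    s = int(c) - FRAGMENT_LENGTH // 2
                    rows.append((chrom, max(0, s), s + FRAGMENT_LENGTH,
                                 f"frag{k:07d}", 0.0, "."))
                    k += 1
        return rows

    pre_mids = np.array([enh_mid[i] for i in pre_idx])
    pre_chroms = [unit_chrom[i] for i in pre_idx]
    dn_mids = np.array([enh_mid[i] for i in dn_idx])
    dn_chroms = [unit_chrom[i] for i in dn_idx]

    # pre-B: small valley at pre-existing sites, dense/unstructured at de novo
    _write_bed_rows(
        ds.mnase_bed("preB"),
        mnase_rows([(pre_mids, pre_chroms, 8, 30.0, 0),
                    (dn_mids, dn_chroms, 0, 30.0, 0)]),
    )
    # iMPhi: pronounced valley at pre-existing, weaker phasing at de novo
    _write_bed_rows(
        ds.mnase_bed("iMPhi"),
        mnase_rows([(pre_mids, pre_chroms, 12, 20.0, 0),
                    (dn_mids, dn_chroms, 8, 30.0, 0)]),
    )

    # --- truth tables & metadata -----------------------------------------
    enh_table = pd.DataFrame(
        {
            "enhancer_id": [f"enh{i + 1:05d}" for i in range(n_units)],
            "chrom": unit_chrom,
            "start": enh_start.astype(int),
            "end": enh_end.astype(int),
            "class": classes,
            "promoter_state": promoter_state,
            "promoter_substate": promoter_substate,
            "gene": gene_ids[:n_units],
            "prebound_pu1": prebound.astype(int),
            "ebf1": ebf1.astype(int),
            "binding_order": order_label,
            "cebpa_min": cebpa_min,
            "pu1_min": pu1_min,
        }
    )
    for ct in cell_types:
        enh_table[f"act_{ct}"] = activity_sel[ct].astype(int)
    for ct in config.occupancy:
        enh_table[f"occ_{ct}"] = occupancy_sel[ct].astype(int)
    enh_table.to_csv(ds.path("truth_enhancers.tsv"), sep="\t", index=False)

    gene_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": gene_chrom,
            "tss": gene_tss,
            "strand": gene_strand,
            "regulation": regulation,
            "fold": np.round(fold, 6),
            "baseline": baseline,
            "near_stable_site": [1] * n_units + [0] * n_desert,
        }
    )
    gene_table.to_csv(ds.path("truth_genes.tsv"), sep="\t", index=False)

    with open(ds.path("genome.tsv"), "w") as fh:
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{name}\t{length}\n")
    config.to_file(ds.path("config.yaml"))

    return ds, TruthTable(enh_table, gene_table)


def load_genome(out_dir: str | Path) -> GenomeModel:
    names, lengths = [], []
    for line in Path(Path(out_dir) / "genome.tsv").read_text().splitlines():
        n, l = line.split("\t")
        names.append(n)
        lengths.append(int(l))
    return GenomeModel(tuple(names), tuple(lengths))


def load_dataset(out_dir: str | Path) -> SyntheticDataset:
    out_dir = Path(out_dir)
    config = ScenarioConfig.from_file(out_dir / "config.yaml")
    return SyntheticDataset(out_dir, config, load_genome(out_dir))
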