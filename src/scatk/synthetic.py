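"""Synthetic scATAC-seq datasets with planted ground truth.

The generator emits everything the pipeline consumes -- genome FASTA, barcode
whitelist, raw fragment records, gene models, term maps and PWMs -- from a
single seeded configuration, together with the truth needed to score every
downstream stage: which barcode belongs to which cell type, where the
accessible peaks are, which peaks carry a planted motif consensus, and which
peaks differ between case and control cells.

What it emulates: several cell types with type-specific accessible peaks, a
multimodal (nucleosome-periodic) fragment-length distribution, fragments
concentrated at peaks and hence near the TSSs placed beside them, ambient
barcodes emitting sparse uniform background, per-base barcode sequencing
errors, PCR duplicates, and a case/control accessibility effect on a subset
of peaks.  It does not emulate read-level sequencing, mappability or
realistic genome composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as skio
from .motifs import Pwm, write_jaspar

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"

AMBIENT = "ambient"


@dataclass
class SyntheticConfig:
    """Every knob of the generator; defaults define the standard dataset
    (2 Mb genome, 300 peaks at 10x per-base signal:background, 3 cell types
    of 200 cells)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_cell_types: int = 3
    cells_per_type: int = 200
    n_ambient_barcodes: int = 2000
    n_peaks: int = 300
    peak_width: int = 1500
    min_peak_gap: int = 2000
    edge_margin: int = 2500
    shared_peak_fraction: float = 0.4
    cross_type_leak: float = 0.1
    signal_to_background: float = 10.0
    fragments_per_cell_mean: float = 200.0
    ambient_fragments_mean: float = 20.0
    barcode_error_rate: float = 0.005
    duplicate_rate: float = 0.2
    frag_len_modes: tuple = ((75.0, 15.0, 0.55), (250.0, 30.0, 0.35),
                             (425.0, 45.0, 0.10))
    planted_motifs: tuple = (("SYN1", 0.8, 0),)
    n_decoy_pwms: int = 1
    motif_length: int = 15
    diff_fraction: float = 0.15
    diff_fold: float = 3.0
    whitelist_size: int = 4000
    barcode_length: int = 16
    gc_content: float = 0.41
    n_genes: int = 1000
    gene_near_peak_fraction: float = 0.25
    n_terms: int = 40
    planted_term_size: int = 25

    def validate(self) -> None:
        counts = [self.n_chroms, self.chrom_length, self.n_cell_types,
                  self.cells_per_type, self.n_ambient_barcodes, self.n_peaks,
                  self.peak_width, self.whitelist_size, self.n_genes,
                  self.n_terms]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        for p in (self.barcode_error_rate, self.duplicate_rate,
                  self.shared_peak_fraction, self.cross_type_leak,
                  self.diff_fraction, self.gc_content,
                  self.gene_near_peak_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0,1]")
        w = sum(m[2] for m in self.frag_len_modes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("frag_len_modes weights must sum to 1")
        if self.diff_fold <= 0:
            raise ValueError("diff_fold must be positive")
        n_barcodes = self.n_cell_types * self.cells_per_type + self.n_ambient_barcodes
        if self.whitelist_size < n_barcodes:
            raise ValueError("whitelist smaller than the barcodes to assign")

    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class SyntheticTruth:
    """Planted ground truth: the oracle for every downstream stage."""

    barcode_to_type: dict[str, str]
    true_peaks: pd.DataFrame  # chrom, start, end
    peak_types: np.ndarray  # -1 = shared, otherwise owning cell type
    type_accessibility: np.ndarray  # n_types x n_peaks relative rates
    planted_motif_sites: pd.DataFrame  # pwm, chrom, start, end, strand, peak
    diff_peaks: np.ndarray  # peak indices with the case/control effect
    planted_term: str | None = None

    def cell_barcodes(self) -> list[str]:
        return sorted(b for b, t in self.barcode_to_type.items() if t != AMBIENT)

    def ambient_barcodes(self) -> list[str]:
        return sorted(b for b, t in self.barcode_to_type.items() if t == AMBIENT)

    def to_dict(self) -> dict:
        return {
            "barcode_to_type": self.barcode_to_type,
            "true_peaks": self.true_peaks.to_dict(orient="list"),
            "peak_types": self.peak_types.tolist(),
            "type_accessibility": self.type_accessibility.tolist(),
            "planted_motif_sites": self.planted_motif_sites.to_dict(orient="list"),
            "diff_peaks": self.diff_peaks.tolist(),
            "planted_term": self.planted_term,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        peak_cols = ["chrom", "start", "end"]
        site_cols = ["pwm", "chrom", "start", "end", "strand", "peak"]
        return cls(
            barcode_to_type=d["barcode_to_type"],
            true_peaks=pd.DataFrame(d["true_peaks"], columns=peak_cols),
            peak_types=np.asarray(d["peak_types"]),
            type_accessibility=np.asarray(d["type_accessibility"]),
            planted_motif_sites=pd.DataFrame(d["planted_motif_sites"],
                                             columns=site_cols),
            diff_peaks=np.asarray(d["diff_peaks"], dtype=int),
            planted_term=d.get("planted_term"),
        )


# --------------------------------------------------------------------------
# whitelist and PWMs


def generate_whitelist(size: int, length: int = 16, min_dist: int = 3,
                       seed: int = 0) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= min_dist (greedy
    rejection sampling), so correction of <=2 substitutions is unambiguous."""
    rng = np.random.default_rng(seed)
    accepted = np.empty((size, length), dtype=np.uint8)
    n = 0
    while n < size:
        cand = rng.integers(0, 4, size=length).astype(np.uint8)
        if n and int((accepted[:n] != cand).sum(axis=1).min()) < min_dist:
            continue
        accepted[n] = cand
        n += 1
    return ["".join(_BASE_STR[c] for c in row) for row in accepted]


def _balanced_consensus(length: int, rng: np.random.Generator) -> str:
    """Roughly GC-balanced consensus so exact-p thresholds stay attainable
    under any bucket background."""
    reps = -(-length // 4)
    pool = np.tile(np.arange(4), reps)[:length]
    rng.shuffle(pool)
    return "".join(_BASE_STR[c] for c in pool)


def default_pwms(config: SyntheticConfig) -> list[Pwm]:
    """One strong PWM per planted motif id plus unplanted decoys.

    Uses its own seed stream so the same PWMs come out no matter where in
    the generation chain they are requested.
    """
    rng = np.random.default_rng(config.seed + 7)
    pwms = []
    ids = [m[0] for m in config.planted_motifs]
    ids += [f"DEC{i + 1}" for i in range(config.n_decoy_pwms)]
    for pid in ids:
        cons = _balanced_consensus(config.motif_length, rng)
        counts = np.full((4, config.motif_length), 5.0)
        for j, b in enumerate(cons):
            counts[_BASE_STR.index(b), j] = 85.0
        pwms.append(Pwm(pid, f"{pid}_MOTIF", counts))
    return pwms


# --------------------------------------------------------------------------
# genome and truth


def _place_peaks(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Distribute peaks over chromosomes with a minimum gap and edge margin."""
    chroms = list(config.chrom_sizes())
    per_chrom = np.full(len(chroms), config.n_peaks // len(chroms))
    per_chrom[: config.n_peaks % len(chroms)] += 1
    rows = []
    w, g, margin = config.peak_width, config.min_peak_gap, config.edge_margin
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        L = config.chrom_length - 2 * margin
        need = k * w + (k - 1) * g
        if need > L:
            raise ValueError(
                f"{k} peaks of {w} bp with {g} bp gaps do not fit in {chrom}"
            )
        slack = rng.integers(0, L - need + 1, size=k)
        slack.sort()
        starts = margin + slack + np.arange(k) * (w + g)
        for s in starts:
            rows.append((chrom, int(s), int(s) + w))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def generate_genome(config: SyntheticConfig):
    """Random genome with planted peaks and motif consensus sequences.

    Returns (genome: chrom -> sequence string, partial SyntheticTruth with
    peak/motif fields filled; barcode assignment happens separately).
    Deterministic given the config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome_codes = {
        c: rng.choice(4, size=n, p=base_p).astype(np.uint8)
        for c, n in config.chrom_sizes().items()
    }

    peaks = _place_peaks(config, rng)
    n_peaks = len(peaks)

    # shared vs type-specific peaks
    peak_types = np.full(n_peaks, -1, dtype=int)
    if config.n_cell_types > 0 and n_peaks:
        n_shared = int(round(config.shared_peak_fraction * n_peaks))
        specific = rng.permutation(n_peaks)[n_shared:]
        peak_types[specific] = np.arange(specific.size) % config.n_cell_types

    # Shared peaks are accessible in every type at rate 1; a type-specific
    # peak is stronger within its own type (compensating for being active in
    # one type only) so every peak has the same expected aggregate coverage
    # and peak strength is not confounded with specificity.
    T = max(config.n_cell_types, 1)
    w_spec = T / (1.0 + config.cross_type_leak * (T - 1))
    acc = np.ones((T, n_peaks))
    for t in range(config.n_cell_types):
        own = peak_types == t
        other = (peak_types >= 0) & (peak_types != t)
        acc[t, own] = w_spec
        acc[t, other] = config.cross_type_leak * w_spec

    # plant motif consensus sequences
    pwms = default_pwms(config)
    pwm_by_id = {p.id: p for p in pwms}
    site_rows = []
    for entry in config.planted_motifs:
        pid, fraction = entry[0], entry[1]
        target = entry[2] if len(entry) > 2 else None
        pwm = pwm_by_id[pid]
        cand = np.arange(n_peaks) if target is None else np.flatnonzero(
            peak_types == target
        )
        k = int(round(fraction * cand.size))
        chosen = rng.choice(cand, size=k, replace=False) if k else np.array([], int)
        for pk in np.sort(chosen):
            row = peaks.iloc[int(pk)]
            margin = 10
            off = int(rng.integers(margin, config.peak_width - pwm.length - margin))
            strand = "+" if rng.random() < 0.5 else "-"
            cons = pwm.consensus()
            if strand == "-":
                cons = _revcomp(cons)
            s = int(row.start) + off
            genome_codes[row.chrom][s : s + pwm.length] = [
                _BASE_STR.index(b) for b in cons
            ]
            site_rows.append((pid, row.chrom, s, s + pwm.length, strand, int(pk)))

    diff_k = int(round(config.diff_fraction * n_peaks))
    diff_peaks = np.sort(rng.choice(n_peaks, size=diff_k, replace=False)) if diff_k \
        else np.array([], dtype=int)

    genome = {c: codes_to_str(v) for c, v in genome_codes.items()}
    truth = SyntheticTruth(
        barcode_to_type={},
        true_peaks=peaks,
        peak_types=peak_types,
        type_accessibility=acc,
        planted_motif_sites=pd.DataFrame(
            site_rows, columns=["pwm", "chrom", "start", "end", "strand", "peak"]
        ),
        diff_peaks=diff_peaks,
    )
    return genome, truth


def codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def assign_barcodes(truth: SyntheticTruth, config: SyntheticConfig,
                    whitelist: list[str], seed: int) -> None:
    """Draw cell and ambient barcodes (disjoint) from the whitelist."""
    rng = np.random.default_rng(seed)
    n_cells = config.n_cell_types * config.cells_per_type
    order = rng.permutation(len(whitelist))
    chosen = [whitelist[i] for i in order[: n_cells + config.n_ambient_barcodes]]
    mapping: dict[str, str] = {}
    for i in range(n_cells):
        mapping[chosen[i]] = f"type{i % max(config.n_cell_types, 1)}"
    for bc in chosen[n_cells:]:
        if bc in mapping:
            raise ValueError("barcode collision between cell and ambient pools")
        mapping[bc] = AMBIENT
    truth.barcode_to_type = mapping


def case_control_split(truth: SyntheticTruth, seed: int) -> dict[str, str]:
    """Half the cells of every type become cases, the rest controls."""
    rng = np.random.default_rng(seed)
    groups: dict[str, str] = {}
    by_type: dict[str, list[str]] = {}
    for bc, t in truth.barcode_to_type.items():
        if t != AMBIENT:
            by_type.setdefault(t, []).append(bc)
    for t in sorted(by_type):
        bcs = sorted(by_type[t])
        order = rng.permutation(len(bcs))
        half = len(bcs) // 2
        for i, j in enumerate(order):
            groups[bcs[j]] = "case" if i < half else "control"
    return groups


def background_fraction(truth: SyntheticTruth, config: SyntheticConfig) -> float:
    """Fraction of cell fragments drawn from uniform background.

    Calibrated so the expected per-base fragment rate inside the
    least-covered peak is ``signal_to_background`` times the genome-wide
    background rate, counting every background source -- the cells' own
    background fragments and the ambient barcodes' uniform emission.
    """
    acc_mean = truth.type_accessibility.mean(axis=0)
    if acc_mean.size == 0 or acc_mean.sum() == 0:
        return 1.0
    genome_len = config.n_chroms * config.chrom_length
    widths = (truth.true_peaks["end"] - truth.true_peaks["start"]).to_numpy()
    per_base_share = (acc_mean / acc_mean.sum() / widths).min()
    n_cell = (config.n_cell_types * config.cells_per_type
              * config.fragments_per_cell_mean)
    n_amb = config.n_ambient_barcodes * config.ambient_fragments_mean
    if n_cell <= 0:
        return 1.0
    a = per_base_share * genome_len  # peak excess rate per unit (1-p)
    s = config.signal_to_background - 1.0
    r = n_amb / n_cell
    p = (a - s * r) / (a + s)
    return float(np.clip(p, 0.0, 1.0))


# --------------------------------------------------------------------------
# fragments


def _draw_lengths(n: int, config: SyntheticConfig, rng) -> np.ndarray:
    modes = np.array(config.frag_len_modes)
    which = rng.choice(len(modes), size=n, p=modes[:, 2])
    lens = rng.normal(modes[which, 0], modes[which, 1])
    return np.maximum(np.round(lens).astype(np.int64), 25)


def _encode_barcodes(barcodes: list[str]) -> np.ndarray:
    joined = "".join(barcodes)
    arr = np.frombuffer(joined.encode(), dtype=np.uint8).reshape(len(barcodes), -1)
    out = np.zeros_like(arr)
    for i, b in enumerate(_BASE_STR):
        out[arr == ord(b)] = i
    return out


def simulate_fragments(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    group_labels: dict[str, str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit the raw (pre-deduplication) fragment record stream.

    Per cell the fragment count is Poisson(fragments_per_cell_mean); each
    fragment lands in a peak of the cell's type (case cells see diff peaks
    multiplied by diff_fold) or in uniform background, its length drawn from
    the configured modes.  Ambient barcodes emit Poisson(ambient_fragments_
    mean) pure-background fragments.  PCR duplicates are injected with the
    configured probability and per-base barcode substitutions applied to each
    emitted record.  Deterministic given the seed (defaults to config seed+1).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    group_labels = group_labels or {}
    chroms = list(config.chrom_sizes())
    chrom_len = config.chrom_length
    peaks = truth.true_peaks
    p_bg = background_fraction(truth, config)

    cells = truth.cell_barcodes()
    ambient = truth.ambient_barcodes()
    if set(cells) & set(ambient):
        raise ValueError("barcode collision between cell and ambient pools")

    frames = []

    # group cells by (type, case/control) so peak probabilities are shared
    key_of = {}
    for bc in cells:
        key_of[bc] = (truth.barcode_to_type[bc], group_labels.get(bc, "control"))
    n_frags_cell = rng.poisson(config.fragments_per_cell_mean, len(cells))

    for key in sorted(set(key_of.values())):
        tname, group = key
        members = [i for i, bc in enumerate(cells) if key_of[bc] == key]
        if not members:
            continue
        t_idx = int(tname.removeprefix("type"))
        weights = truth.type_accessibility[t_idx].astype(float).copy()
        if group == "case" and truth.diff_peaks.size:
            weights[truth.diff_peaks] *= config.diff_fold
        total = weights.sum()
        counts = n_frags_cell[members]
        n_tot = int(counts.sum())
        if n_tot == 0:
            continue
        bc_rep = np.repeat([cells[i] for i in members], counts)
        is_bg = rng.random(n_tot) < p_bg if total > 0 else np.ones(n_tot, bool)
        lens = _draw_lengths(n_tot, config, rng)
        start = np.empty(n_tot, dtype=np.int64)
        chrom_idx = np.empty(n_tot, dtype=np.int64)
        n_peak = int((~is_bg).sum())
        if n_peak:
            pk = rng.choice(len(peaks), size=n_peak, p=weights / total)
            widths = (peaks["end"] - peaks["start"]).to_numpy()
            # both transposition events sit in open chromatin: the fragment
            # lies entirely inside its peak (lengths capped at peak width)
            plen = np.minimum(lens[~is_bg], widths[pk])
            lens[~is_bg] = plen
            start[~is_bg] = peaks["start"].to_numpy()[pk] + (
                rng.random(n_peak) * (widths[pk] - plen + 1)
            ).astype(np.int64)
            chrom_map = {c: i for i, c in enumerate(chroms)}
            chrom_idx[~is_bg] = peaks["chrom"].map(chrom_map).to_numpy()[pk]
        n_bg = n_tot - n_peak
        if n_bg:
            chrom_idx[is_bg] = rng.integers(0, len(chroms), size=n_bg)
            blen = np.minimum(lens[is_bg], chrom_len)
            lens[is_bg] = blen
            mid = rng.integers(0, chrom_len, size=n_bg)
            start[is_bg] = np.clip(mid - blen // 2, 0, chrom_len - blen)
        frames.append(_records(bc_rep, chrom_idx, start, lens, chroms))

    if ambient:
        n_frags_amb = rng.poisson(config.ambient_fragments_mean, len(ambient))
        n_tot = int(n_frags_amb.sum())
        if n_tot:
            bc_rep = np.repeat(ambient, n_frags_amb)
            chrom_idx = rng.integers(0, len(chroms), size=n_tot)
            lens = np.minimum(_draw_lengths(n_tot, config, rng), chrom_len)
            mid = rng.integers(0, chrom_len, size=n_tot)
            start = np.clip(mid - lens // 2, 0, chrom_len - lens)
            frames.append(_records(bc_rep, chrom_idx, start, lens, chroms))

    if not frames:
        return pd.DataFrame(columns=skio.FRAGMENT_COLUMNS).astype(
            {"start": np.int64, "end": np.int64, "count": np.int64}
        )
    df = pd.concat(frames, ignore_index=True)

    # PCR duplicates: re-emit a record with probability duplicate_rate
    dup = np.flatnonzero(np.asarray(rng.random(len(df)) < config.duplicate_rate))
    if dup.size:
        df = pd.concat([df, df.iloc[dup]], ignore_index=True)

    # per-record barcode substitution errors
    if config.barcode_error_rate > 0 and len(df):
        codes = _encode_barcodes(df["barcode"].tolist())
        err = rng.random(codes.shape) < config.barcode_error_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum()))
            codes[err] = (codes[err] + shift) % 4
            bad_rows = np.flatnonzero(err.any(axis=1))
            observed = df["barcode"].to_numpy(dtype=object)
            for r in bad_rows:
                observed[r] = "".join(_BASE_STR[c] for c in codes[r])
            df["barcode"] = observed

    df = df.sort_values(["chrom", "start", "end", "barcode"],
                        kind="mergesort").reset_index(drop=True)
    return df


def _records(bc_rep, chrom_idx, start, lens, chroms):
    return pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(chrom_idx, categories=chroms)
            .astype(str),
            "start": start,
            "end": start + lens,
            "barcode": bc_rep,
            "count": np.ones(len(bc_rep), dtype=np.int64),
        }
    )


# --------------------------------------------------------------------------
# gene models, term maps, full datasets


def generate_annotation(truth: SyntheticTruth, config: SyntheticConfig,
                        seed: int):
    """Gene models (BED6) and a term map with one planted enriched term.

    A configurable fraction of genes get a TSS within 300 bp of a peak edge
    (so peak-related gene sets are non-trivial); the rest land anywhere.
    The planted term is drawn from peak-proximal genes, every other term is a
    uniform draw, giving the enrichment stage a positive control.
    """
    rng = np.random.default_rng(seed)
    chroms = list(config.chrom_sizes())
    rows = []
    n_near = int(round(config.gene_near_peak_fraction * config.n_genes))
    peaks = truth.true_peaks
    near_flags = []
    for i in range(config.n_genes):
        name = f"G{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        body = int(rng.integers(500, 2000))
        near = i < n_near and len(peaks) > 0
        if near:
            # accessible promoter: TSS inside the peak interval
            pk = peaks.iloc[int(rng.integers(len(peaks)))]
            tss = int(pk.start) + int(rng.integers(50, config.peak_width - 50))
            chrom = pk.chrom
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            tss = int(rng.integers(config.edge_margin,
                                   config.chrom_length - config.edge_margin))
        tss = int(np.clip(tss, body, config.chrom_length - body - 1))
        if strand == "+":
            start, end = tss, tss + body
        else:
            start, end = tss - body + 1, tss + 1
        rows.append((chrom, start, end, name, 0, strand))
        near_flags.append(near)
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                        "score", "strand"])

    names = genes["name"].tolist()
    near_names = [n for n, f in zip(names, near_flags) if f]
    term_map: dict[str, set[str]] = {}
    planted_term = None
    if config.n_terms > 0 and names:
        pool = near_names if near_names else names
        k = min(config.planted_term_size, len(pool))
        planted_term = "TERM_PLANTED"
        term_map[planted_term] = set(
            rng.choice(pool, size=k, replace=False).tolist()
        )
        for i in range(config.n_terms - 1):
            size = int(rng.integers(10, 51))
            size = min(size, len(names))
            term_map[f"TERM{i:03d}"] = set(
                rng.choice(names, size=size, replace=False).tolist()
            )
    truth.planted_term = planted_term
    return genes, term_map


@dataclass
class SyntheticDataset:
    """Everything one seeded generation produces, ready to write or analyze."""

    config: SyntheticConfig
    genome: dict[str, str]
    truth: SyntheticTruth
    whitelist: list[str]
    fragments: pd.DataFrame
    genes: pd.DataFrame
    term_map: dict[str, set[str]]
    pwms: list
    groups: dict[str, str] = field(default_factory=dict)


def generate_dataset(config: SyntheticConfig,
                     with_groups: bool = True) -> SyntheticDataset:
    """Run the full generation chain from one config, deterministically."""
    genome, truth = generate_genome(config)
    whitelist = generate_whitelist(config.whitelist_size, config.barcode_length,
                                   seed=config.seed + 11)
    assign_barcodes(truth, config, whitelist, seed=config.seed + 12)
    groups = case_control_split(truth, seed=config.seed + 13) if with_groups else {}
    fragments = simulate_fragments(truth, config, group_labels=groups,
                                   seed=config.seed + 1)
    genes, term_map = generate_annotation(truth, config, seed=config.seed + 14)
    pwms = default_pwms(config)
    return SyntheticDataset(config, genome, truth, whitelist, fragments,
                            genes, term_map, pwms, groups)


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the complete dataset as plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "whitelist": outdir / "whitelist.txt",
        "fragments": outdir / "fragments.tsv",
        "genes": outdir / "genes.bed",
        "terms": outdir / "terms.tsv",
        "pwms": outdir / "motifs.jaspar",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    skio.write_fasta(ds.genome, paths["genome"])
    skio.write_whitelist(ds.whitelist, paths["whitelist"])
    skio.write_fragments(ds.fragments, paths["fragments"])
    skio.write_bed(ds.genes, paths["genes"])
    skio.write_term_map(ds.term_map, paths["terms"])
    write_jaspar(ds.pwms, paths["pwms"])
    skio.write_json(ds.truth.to_dict(), paths["truth"])
    skio.write_json(asdict(ds.config), paths["config"])
    if ds.groups:
        paths["groups"] = outdir / "groups.tsv"
        pd.Series(ds.groups, name="group").rename_axis("barcode").to_csv(
            paths["groups"], sep="\t", header=False
        )
    return paths
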