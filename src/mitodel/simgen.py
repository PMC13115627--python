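"""Synthetic heteroplasmic mtDNA long-read data with truth tables.

The generator emulates the study conditions of an amplification-free HiFi
mtDNA experiment: a circular genome (16,569 bp by default), a molecule
population mixing intact genomes and deletion-bearing genomes at
configured heteroplasmy fractions, and sheared long-read fragments
(lognormal length, median ~10 kb) sampled uniformly around each circular
molecule.  Reads spanning a deletion junction carry the deletion as a
CIGAR ``D`` operation; fragments crossing the reference origin are emitted
as a primary + supplementary record pair so alignments stay linear on the
contig.  Reads are error-free by default; an optional substitution rate
adds mismatches but never indels.

Two modelling choices keep the read-count / RNR2-coverage heteroplasmy
estimator unbiased, mirroring the physics of shearing:

* a fragment's molecule class is drawn with probability proportional to
  ``fraction x molecule length`` (shearing yields fragment counts
  proportional to molecule mass);
* fragment length is drawn from one distribution truncated to the shortest
  molecule present, so length is independent of class.

Under these choices the expected number of junction-spanning reads for a
deletion at molecule fraction ``f`` equals ``f`` times the expected depth
at any non-deleted position, so the estimator recovers ``f`` up to
binomial noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .refmodel import MitoReference, RCRS_LENGTH, circular_gap, scaled_regions

_BASES = np.array(list("ACGT"))

DEFAULT_READ_LEN_MODEL = ("lognormal", {"median": 10000.0, "sigma": 0.35})
MAX_PLANT_MH = 20  # beyond the measurement window cap


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated sample.

    ``deletions`` is a list of ``(b5, b3, fraction)`` tuples: molecule
    fractions of each deletion species (the remainder of the population is
    intact).  ``planted_mh`` maps a junction ``(b5, b3)`` to the exact
    microhomology length to engineer at that junction.
    """

    genome_len: int = RCRS_LENGTH
    seed: int = 0
    deletions: tuple[tuple[int, int, float], ...] = ()
    mean_coverage: float = 800.0
    read_len_model: tuple[str, dict] = DEFAULT_READ_LEN_MODEL
    min_read_len: int = 1000
    substitution_rate: float = 0.0
    planted_mh: dict = field(default_factory=dict)
    sample_id: str = "sim"
    contig: str = "chrM"
    wrap_mode: str = "split"  # "split" | "linear"

    def __post_init__(self) -> None:
        if self.genome_len < 200:
            raise ValueError("genome_len must be >= 200")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        total = sum(f for _, _, f in self.deletions)
        if any(f < 0 for _, _, f in self.deletions) or total > 1 + 1e-9:
            raise ValueError("deletion fractions must be >= 0 and sum <= 1")
        for b5, b3, _ in self.deletions:
            if not (1 <= b5 < b3 <= self.genome_len):
                raise ValueError(
                    f"deletion ({b5}, {b3}) must satisfy 1 <= b5 < b3 <= L; "
                    "the generator plants non-origin-spanning deletions"
                )
            if not (0 < circular_gap(b5, b3, self.genome_len) < self.genome_len):
                raise ValueError(f"deletion ({b5}, {b3}) has invalid size")
        if self.wrap_mode not in ("split", "linear"):
            raise ValueError("wrap_mode must be 'split' or 'linear'")
        if not (0 <= self.substitution_rate < 1):
            raise ValueError("substitution_rate must be in [0, 1)")


@dataclass(frozen=True)
class SamRecord:
    qname: str
    flag: int
    pos: int  # 1-based leftmost
    cigar: str
    seq: str
    mapq: int = 60

    def to_line(self, contig: str) -> str:
        return "\t".join(
            [self.qname, str(self.flag), contig, str(self.pos), str(self.mapq),
             self.cigar, "*", "0", "0", self.seq, "*"]
        )


@dataclass
class SimulatedSample:
    config: SimConfig
    records: list[SamRecord]
    truth: pd.DataFrame  # read_id, molecule_class, deletion_id, spans_junction
    expected: dict

    def sam_text(self) -> str:
        cfg = self.config
        header = [
            "@HD\tVN:1.6\tSO:coordinate",
            f"@SQ\tSN:{cfg.contig}\tLN:{cfg.genome_len}",
            "@PG\tID:mitodel-simgen\tPN:mitodel",
        ]
        body = [r.to_line(cfg.contig) for r in sorted(self.records, key=lambda r: (r.pos, r.qname, r.flag))]
        return "\n".join(header + body) + "\n"

    def write_sam(self, path: str | Path) -> None:
        Path(path).write_text(self.sam_text())


def simulate_reference(genome_len: int = RCRS_LENGTH, seed: int = 0) -> MitoReference:
    """Random circular A/C/G/T genome with proportionally scaled regions."""
    if genome_len < 200:
        raise ValueError("genome_len must be >= 200")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(_BASES, size=genome_len))
    return MitoReference(
        name="chrM", sequence=seq, regions=scaled_regions(genome_len)
    )


def _set_base(seq: list[str], pos: int, base: str, length: int) -> None:
    seq[(pos - 1) % length] = base


def _get_base(seq: list[str], pos: int, length: int) -> str:
    return seq[(pos - 1) % length]


def _different_base(avoid: str) -> str:
    for b in "ACGT":
        if b != avoid:
            return b
    raise AssertionError("unreachable")


def plant_microhomology(ref: MitoReference, b5: int, b3: int, k: int) -> MitoReference:
    """Engineer exactly ``k`` bases of junction microhomology at (b5, b3).

    Copies the ``k`` bases starting at ``b3`` onto the ``k`` bases starting
    at ``b5``, then breaks any chance extension of the run one base beyond
    each end so the junction-anchored measurement returns exactly ``k``.
    ``k = 0`` leaves the sequence unchanged.
    """
    if k < 0 or k > MAX_PLANT_MH:
        raise ValueError(f"planted homology must be in [0, {MAX_PLANT_MH}]")
    if k == 0:
        return ref
    L = ref.length
    seq = list(ref.sequence)
    for i in range(k):
        _set_base(seq, b5 + i, _get_base(seq, b3 + i, L), L)
    # break forward extension at offset k and backward extension at -1
    if _get_base(seq, b5 + k, L) == _get_base(seq, b3 + k, L):
        _set_base(seq, b5 + k, _different_base(_get_base(seq, b3 + k, L)), L)
    if _get_base(seq, b5 - 1, L) == _get_base(seq, b3 - 1, L):
        _set_base(seq, b5 - 1, _different_base(_get_base(seq, b3 - 1, L)), L)
    return ref.with_sequence("".join(seq))


def apply_planted_homology(ref: MitoReference, config: SimConfig) -> MitoReference:
    for (b5, b3), k in config.planted_mh.items():
        ref = plant_microhomology(ref, b5, b3, k)
    return ref


class _MoleculeClass:
    """Coordinate bookkeeping for one molecule species on the circle."""

    def __init__(self, name: str, genome_len: int, deletion: tuple[int, int] | None):
        self.name = name
        self.deletion = deletion
        if deletion is None:
            self.length = genome_len
            self._b5 = None
        else:
            b5, b3 = deletion
            self.del_len = circular_gap(b5, b3, genome_len)
            self.length = genome_len - self.del_len
            self._b5 = b5
        self._L = genome_len

    def ref_positions(self, start: int, rl: int) -> np.ndarray:
        """Reference positions (1-based) covered by a fragment of length
        ``rl`` starting at molecule index ``start`` (0-based, circular)."""
        idx = (start + np.arange(rl)) % self.length
        if self._b5 is None:
            return idx + 1
        # non-wrapping deletion [b5, b3): molecule index i maps to ref i+1
        # below the junction and i+1+del_len at or above it
        return np.where(idx < self._b5 - 1, idx + 1, idx + 1 + self.del_len)


def _draw_read_length(rng: np.random.Generator, config: SimConfig, max_len: int) -> int:
    name, params = config.read_len_model
    lo = min(config.min_read_len, max_len)
    if name == "lognormal":
        mu = float(np.log(params.get("median", 10000.0)))
        sigma = float(params.get("sigma", 0.35))
        rl = int(rng.lognormal(mu, sigma))
    elif name == "constant":
        rl = int(params["length"])
    else:
        raise ValueError(f"unknown read length model {name!r}")
    return int(np.clip(rl, lo, max_len))


def _cigar_and_chunks(positions: np.ndarray) -> list[tuple[int, list[tuple[str, int]], int, int]]:
    """Split a read's covered reference positions into linear chunks.

    Returns a list of ``(ref_start, cigar_ops, q_offset, q_len)`` tuples;
    one chunk for linear reads, two when the fragment crosses the origin.
    Within a chunk, forward jumps become D operations.
    """
    diffs = np.diff(positions)
    wrap_points = np.nonzero(diffs < 0)[0]
    bounds = [0, *[int(w) + 1 for w in wrap_points], len(positions)]
    chunks = []
    for lo, hi in zip(bounds, bounds[1:]):
        sub = positions[lo:hi]
        ops: list[tuple[str, int]] = []
        run_start = 0
        for j in range(1, len(sub) + 1):
            if j == len(sub) or sub[j] != sub[j - 1] + 1:
                ops.append(("M", j - run_start))
                if j < len(sub):
                    ops.append(("D", int(sub[j] - sub[j - 1] - 1)))
                run_start = j
        chunks.append((int(sub[0]), ops, lo, hi - lo))
    return chunks


def _ops_to_string(ops: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def simulate_sample(ref: MitoReference, config: SimConfig) -> SimulatedSample:
    """Simulate SAM alignment records and a truth table for one sample.

    Fragments are drawn until the cumulative read bases reach
    ``mean_coverage x genome_len``; each fragment picks a molecule class
    (mass-weighted), a uniform circular start, and is emitted with an exact
    CIGAR against the reference.  Deterministic for a given config seed.
    """
    if ref.length != config.genome_len:
        raise ValueError("reference length does not match config.genome_len")
    ref = apply_planted_homology(ref, config)
    rng = np.random.default_rng(config.seed)
    L = config.genome_len

    classes = [_MoleculeClass("intact", L, None)]
    fractions = [1.0 - sum(f for _, _, f in config.deletions)]
    for b5, b3, f in config.deletions:
        classes.append(_MoleculeClass(f"del_{b5}_{b3}", L, (b5, b3)))
        fractions.append(f)
    weights = np.array([f * c.length for f, c in zip(fractions, classes)])
    if weights.sum() <= 0:
        raise ValueError("no molecule mass: all fractions zero?")
    weights = weights / weights.sum()
    shortest = min(c.length for c in classes)

    target_bases = config.mean_coverage * L
    records: list[SamRecord] = []
    truth_rows = []
    total = 0
    i = 0
    while total < target_bases:
        rl = _draw_read_length(rng, config, max_len=shortest - 1)
        ci = int(rng.choice(len(classes), p=weights))
        mol = classes[ci]
        start = int(rng.integers(0, mol.length))
        if config.wrap_mode == "linear":
            start = int(rng.integers(0, mol.length - rl + 1))
        positions = mol.ref_positions(start, rl)
        read_id = f"read_{i:06d}"
        seq = np.array([ref.sequence[p - 1] for p in positions])
        if config.substitution_rate > 0:
            hit = rng.random(rl) < config.substitution_rate
            for j in np.nonzero(hit)[0]:
                seq[j] = rng.choice(_BASES[_BASES != seq[j]])
        full_seq = "".join(seq)
        chunks = _cigar_and_chunks(positions)
        spans = mol.deletion is not None and any(
            op == "D" for _, ops, _, _ in chunks for op, _ in ops
        )
        for ck, (ref_start, ops, q_off, q_len) in enumerate(chunks):
            lead, trail = q_off, rl - q_off - q_len
            cigar_parts = []
            if lead:
                cigar_parts.append(("S", lead))
            cigar_parts.extend(ops)
            if trail:
                cigar_parts.append(("S", trail))
            flag = 0 if ck == 0 else 2048
            records.append(
                SamRecord(
                    qname=read_id,
                    flag=flag,
                    pos=ref_start,
                    cigar=_ops_to_string(cigar_parts),
                    seq=full_seq,
                )
            )
        truth_rows.append(
            dict(
                read_id=read_id,
                molecule_class=mol.name,
                deletion_id=mol.name if mol.deletion else "",
                spans_junction=spans,
                read_len=rl,
            )
        )
        total += rl
        i += 1

    truth = pd.DataFrame(truth_rows)
    expected = {
        "sample_id": config.sample_id,
        "genome_len": L,
        "mean_coverage_target": config.mean_coverage,
        "junctions": [
            {"b5": b5, "b3": b3, "fraction": f,
             "heteroplasmy_pct": 100.0 * f,
             "del_len": circular_gap(b5, b3, L)}
            for b5, b3, f in config.deletions
        ],
        "total_heteroplasmy_pct": 100.0 * sum(f for _, _, f in config.deletions),
        "n_reads": len(truth),
        "seed": config.seed,
    }
    return SimulatedSample(config=config, records=records, truth=truth, expected=expected)


def simulate_dataset(config: SimConfig) -> tuple[MitoReference, SimulatedSample]:
    """Reference (with planted homology) plus one simulated sample."""
    ref = simulate_reference(config.genome_len, config.seed)
    ref = apply_planted_homology(ref, config)
    sim = simulate_sample(ref, replace(config, planted_mh={}))
    return ref, sim


#: Named scenario presets mirroring the cohort structure: a single
#: recurrent junction at high heteroplasmy (SLSMD), five distinct
#: junctions at low fractions (MMD), and a deletion-free negative.
PRESETS: dict[str, tuple[tuple[int, int, float], ...]] = {
    "slsmd": ((8470, 13447, 0.35),),
    "mmd": (
        (5500, 9500, 0.04),
        (6500, 10500, 0.04),
        (7500, 12000, 0.04),
        (8470, 13447, 0.04),
        (9000, 14500, 0.04),
    ),
    "negative": (),
}


def preset_config(name: str, seed: int = 0, mean_coverage: float = 800.0,
                  **overrides) -> SimConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    return SimConfig(
        deletions=PRESETS[name],
        seed=seed,
        mean_coverage=mean_coverage,
        sample_id=name,
        **overrides,
    )


def write_bundle(ref: MitoReference, sim: SimulatedSample, outdir: str | Path) -> dict:
    """Write reference FASTA, SAM, truth TSV and truth JSON to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "reference.fasta"
    with open(fasta, "w") as fh:
        fh.write(f">{sim.config.contig}\n")
        for i in range(0, ref.length, 70):
            fh.write(ref.sequence[i : i + 70] + "\n")
    sam = outdir / "reads.sam"
    sim.write_sam(sam)
    truth_tsv = outdir / "truth.tsv"
    sim.truth.to_csv(truth_tsv, sep="\t", index=False)
    truth_json = outdir / "truth.json"
    truth_json.write_text(json.dumps(sim.expected, indent=2) + "\n")
    return {"fasta": fasta, "sam": sam, "truth_tsv": truth_tsv, "truth_json": truth_json}
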