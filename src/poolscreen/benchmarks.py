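"""Self-contained calibration experiments and independent oracles.

These routines measure the pipeline against ground truth it did not see:
a brute-force all-offset alignment oracle, an end-to-end spike-in
recovery benchmark, a null (no spiked mutation) calibration of the
quality filter, and mutational-spectrum recovery. They are used both by
the test suite and by ``scripts/acceptance.py``.

All randomness flows from explicit integer seeds; derived seeds are
spawned with :class:`numpy.random.SeedSequence` and kept below 2^31.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .align import (
    KmerIndex,
    MAX_PROBE_MISMATCHES,
    STATUS_AMBIGUOUS,
    STATUS_TOO_MANY,
    STATUS_UNIQUE,
    STATUS_UNMAPPED,
    align_batch,
    align_read,
)
from .calling import CallerConfig, call_and_rank
from .reference import OrfReference, reverse_complement
from .simulate import (
    MutagenesisConfig,
    MutantAllele,
    QualityModel,
    ReadSimConfig,
    draw_spikes,
    mutagenize,
    simulate_reads,
    spiked_pool,
)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def brute_force_align(
    amplicon: str, reads: Sequence[str], chunk: int = 100
) -> list[dict]:
    """All-offset × both-strand scan; same status semantics as the aligner.

    Independent oracle: mismatch counts are computed for *every* placement
    by direct array comparison, with no seeding. Returns per read a dict
    with status and, when unique, 0-based start, strand, mismatch count
    and the amplicon offset of the mismatch (None for exact reads).
    """
    L = len(amplicon)
    rl = len(reads[0])
    if any(len(r) != rl for r in reads):
        raise ValueError("oracle requires equal-length reads")
    ref_codes = _encode(amplicon)
    windows = sliding_window_view(ref_codes, rl)  # (W, rl)
    fwd = np.stack([_encode(r) for r in reads])
    rev = np.stack([_encode(reverse_complement(r)) for r in reads])

    results: list[dict] = []
    if rl > L:
        return [{"status": STATUS_UNMAPPED} for _ in reads]
    for lo in range(0, len(reads), chunk):
        hi = min(lo + chunk, len(reads))
        mm_f = (fwd[lo:hi, None, :] != windows[None, :, :]).sum(-1)  # (B, W)
        mm_r = (rev[lo:hi, None, :] != windows[None, :, :]).sum(-1)
        for b in range(hi - lo):
            mf, mr = mm_f[b], mm_r[b]
            best = int(min(mf.min(), mr.min()))
            n_best = int((mf == best).sum() + (mr == best).sum())
            if best <= 1:
                if n_best > 1:
                    results.append({"status": STATUS_AMBIGUOUS})
                    continue
                if (mf == best).any():
                    start, strand, seq_codes = int(mf.argmin()), "+", fwd[lo + b]
                else:
                    start, strand, seq_codes = int(mr.argmin()), "-", rev[lo + b]
                mism_off = None
                if best == 1:
                    mism_off = int(
                        np.flatnonzero(seq_codes != ref_codes[start : start + rl])[0]
                    ) + start
                results.append(
                    {
                        "status": STATUS_UNIQUE,
                        "start": start,
                        "strand": strand,
                        "n_mismatches": best,
                        "mismatch_offset": mism_off,
                    }
                )
            elif best <= MAX_PROBE_MISMATCHES:
                results.append({"status": STATUS_TOO_MANY})
            else:
                results.append({"status": STATUS_UNMAPPED})
    return results


def make_duplicated_reference(
    seed: int, length: int = 1998, dup_span: tuple[int, int] = (300, 450), dup_at: int = 1200
) -> OrfReference:
    """Random flankless reference carrying an internal duplicated segment,
    so exact reads from the segment are genuinely ambiguous."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, length)].tobytes().decode()
    lo, hi = dup_span
    seg = seq[lo:hi]
    seq = seq[:dup_at] + seg + seq[dup_at + len(seg) :]
    return OrfReference(id="dup_ref", seq=seq[: 3 * (len(seq) // 3)])


def oracle_read_set(
    ref: OrfReference,
    n_reads: int,
    seed: int,
    read_length: int = 100,
    max_subs: int = 3,
    dup_span: tuple[int, int] = (300, 450),
    random_fraction: float = 0.05,
    dup_fraction: float = 0.05,
) -> list[str]:
    """Random reads for the oracle check: reference substrings from both
    strands with 0..max_subs injected substitutions, a slice targeting the
    duplicated segment, and a slice of fully random (unmappable) reads."""
    rng = np.random.default_rng(seed)
    amplicon = ref.amplicon
    L = len(amplicon)
    bases = "ACGT"
    reads = []
    for _ in range(n_reads):
        u = rng.random()
        if u < random_fraction:
            reads.append("".join(bases[i] for i in rng.integers(0, 4, read_length)))
            continue
        if u < random_fraction + dup_fraction:
            start = int(rng.integers(dup_span[0], dup_span[1] - read_length + 1))
            n_subs = 0  # exact duplicated-segment read: must come out ambiguous
        else:
            start = int(rng.integers(0, L - read_length + 1))
            n_subs = int(rng.integers(0, max_subs + 1))
        read = list(amplicon[start : start + read_length])
        if n_subs:
            for pos in rng.choice(read_length, size=n_subs, replace=False):
                read[pos] = bases[(bases.index(read[pos]) + int(rng.integers(1, 4))) % 4]
        read = "".join(read)
        if rng.random() < 0.5:
            read = reverse_complement(read)
        reads.append(read)
    return reads


def aligner_oracle_check(seed: int, n_reads: int = 10_000, k: int = 25) -> dict:
    """Fraction of reads where the k-mer aligner agrees with the brute-force
    oracle on status and, for unique reads, placement and mismatch."""
    s_ref, s_reads = _sub_seeds(seed, 2)
    ref = make_duplicated_reference(s_ref)
    reads = oracle_read_set(ref, n_reads, s_reads)
    index = KmerIndex(ref, k=k)
    quals = [40] * len(reads[0])
    oracle = brute_force_align(ref.amplicon, reads)
    n_agree = 0
    for i, read in enumerate(reads):
        rec = align_read(index, read, quals, read_id=f"r{i}")
        o = oracle[i]
        if rec.status != o["status"]:
            continue
        if rec.status == STATUS_UNIQUE:
            if rec.ref_start != o["start"] or rec.strand != o["strand"]:
                continue
            if rec.n_mismatches != o["n_mismatches"]:
                continue
            if o["mismatch_offset"] is not None:
                if not rec.mismatches:
                    continue
                obs = rec.mismatches[0]
                # flankless reference: orf_pos maps 1:1 onto the amplicon
                if obs.orf_pos != o["mismatch_offset"] + 1:
                    continue
        n_agree += 1
    return {
        "n_reads": n_reads,
        "n_agree": n_agree,
        "agreement_fraction": n_agree / n_reads,
    }


def spike_in_benchmark(
    seed: int,
    ref: OrfReference,
    n_alleles: int = 1000,
    n_spikes: int = 30,
    n_reads: int = 60_000,
    gc_to_at_fraction: float = 0.9,
    abundance_sigma: float = 1.0,
    caller: CallerConfig = CallerConfig(),
    workdir: Optional[Path] = None,
) -> dict:
    """End-to-end parameter recovery on a pool with known spiked mutations.

    Simulates a pool of single-mutant alleles over ``n_spikes`` known
    substitutions with log-normal colony abundances and quality-coupled
    sequencing errors, runs align → call at the configured thresholds,
    and scores the top-``n_spikes`` of the ranked table against the
    spiked truth (precision/recall) plus Spearman agreement between
    supporting reads and realized truth coverage.
    """
    s_spikes, s_pool, s_reads = _sub_seeds(seed, 3)
    spikes = draw_spikes(ref, n_spikes, gc_to_at_fraction, seed=s_spikes)
    pool = spiked_pool(ref, spikes, n_alleles, abundance_sigma, seed=s_pool)
    cfg = ReadSimConfig(n_reads=n_reads, seed=s_reads)

    def run(dirpath: Path) -> dict:
        fastq = dirpath / "pool.fastq"
        truth = dirpath / "truth.tsv"
        summary = simulate_reads(ref, pool, cfg, fastq, truth)
        index = KmerIndex(ref)
        batch = align_batch(index, fastq)
        table = call_and_rank(ref, batch["observations"], caller)
        spike_set = set(spikes)
        top = {e.key() for e in table.entries[:n_spikes]}
        tp = len(top & spike_set)
        coverage = summary["per_mutation_coverage"]
        support = {e.key(): e.supporting_reads for e in table.entries}
        called_spikes = [s for s in spikes if s in support]
        rho = float("nan")
        if len(called_spikes) >= 3:
            rho = float(
                stats.spearmanr(
                    [coverage.get(s, 0) for s in called_spikes],
                    [support[s] for s in called_spikes],
                ).statistic
            )
        return {
            "n_spikes": n_spikes,
            "n_reads": n_reads,
            "precision": tp / max(len(top), 1),
            "recall": tp / n_spikes,
            "spearman_support_vs_coverage": rho,
            "min_spike_coverage": min(coverage.get(s, 0) for s in spikes),
            "threshold_reads": table.threshold_reads,
            "table": table,
            "align_summary": {k: v for k, v in batch.items() if k != "observations"},
        }

    if workdir is not None:
        workdir.mkdir(parents=True, exist_ok=True)
        return run(workdir)
    with tempfile.TemporaryDirectory() as tmp:
        return run(Path(tmp))


def null_calibration(
    seed: int,
    ref: OrfReference,
    n_reads: int = 20_000,
    quality_model: Optional[QualityModel] = None,
    min_quality: int = 38,
) -> dict:
    """Zero spiked mutations, error channel on: compare the post-filter
    call count with the analytic expectation under the quality model.

    A base yields a kept observation iff it miscalls (prob 10^(-Q/10)),
    its quality passes the filter, and no other base in the read erred
    (the <=1-mismatch rule drops two-error reads); the expectation is
    n_reads * L * E[p·1(Q>=Q_min)] * (1 - E[p])^(L-1) with Poisson
    (binomial) sigma.
    """
    qm = quality_model or QualityModel.hiseq()
    # flankless copy so every read base sits inside the ORF
    flankless = OrfReference(id=ref.id, seq=ref.seq)
    cfg = ReadSimConfig(n_reads=n_reads, quality_model=qm, error_coupling=True, seed=seed)
    with tempfile.TemporaryDirectory() as tmp:
        fastq = Path(tmp) / "null.fastq"
        simulate_reads(flankless, [MutantAllele(allele_id="wt")], cfg, fastq)
        index = KmerIndex(flankless)
        batch = align_batch(index, fastq)
    caller = CallerConfig(
        min_quality=min_quality, top_n=10**9, include_synonymous=True, include_stops=True
    )
    table = call_and_rank(flankless, batch["observations"], caller)
    observed = table.totals["calls_passing_quality"]
    rl = cfg.read_length
    p_err = qm.mean_error_prob()
    p_read = rl * qm.mean_kept_error_prob(min_quality) * (1.0 - p_err) ** (rl - 1)
    expected = n_reads * p_read
    sigma = float(np.sqrt(n_reads * p_read * (1.0 - p_read)))
    return {
        "n_reads": n_reads,
        "observed_calls": observed,
        "expected_calls": expected,
        "sigma": sigma,
        "z": (observed - expected) / sigma,
    }


def spectrum_recovery(
    seed: int,
    ref: OrfReference,
    fractions: Sequence[float] = (0.5, 0.9, 1.0),
    n_alleles: int = 3000,
    mean_mutations: float = 1.5,
) -> dict[float, dict]:
    """Mutagenize at each configured GC→AT fraction and audit the realized
    spectrum against the binomial expectation."""
    from .landscape import spectrum_audit

    out: dict[float, dict] = {}
    for f, s in zip(fractions, _sub_seeds(seed, len(fractions))):
        cfg = MutagenesisConfig(
            mean_mutations_per_plasmid=mean_mutations, gc_to_at_fraction=f, seed=s
        )
        pool = mutagenize(ref, cfg, n_alleles, abundance_model="uniform")
        pairs = [(rb, ab) for a in pool for (_, rb, ab) in a.substitutions]
        audit = spectrum_audit(pairs)
        assert audit is not None
        n = audit["n_calls"]
        sigma = float(np.sqrt(f * (1 - f) / n))
        out[f] = {
            "configured": f,
            "observed": audit["fraction_gc_to_at"],
            "n_mutations": n,
            "sigma": sigma,
            "within_3sigma": abs(audit["fraction_gc_to_at"] - f) <= 3 * sigma,
        }
    return out
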