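"""Per-position pileup engine with a deterministic parallel contract.

Counts filtered read bases at arbitrary lists of single-nucleotide
positions (typically SNPs) from coordinate-sorted, indexed BAM files.
Unlike region pileups, each site is resolved by random access, which is
what makes sparse SNP lists fast.

Filtering semantics:

* ``min_base_quality`` (mbq) drops individual bases below the threshold.
* ``min_read_quality`` (mrq) is interpreted as the read *mapping* quality,
  the natural per-read score in alignment files.
* Secondary, supplementary and duplicate-marked alignments are excluded by
  default (``include_flagged`` re-admits them).
* Deletions and reference skips at the site contribute nothing; bases other
  than A/C/G/T are excluded from counts and depth.
* Both mates of an overlapping pair are counted by default;
  ``dedup_mates=True`` counts each fragment once.

``min_depth`` (mdc) is deliberately *not* applied here — downstream
consumers (genotyping, ASE) own that threshold so the pileup table stays
complete.

Parallel execution is a pure performance feature: for any worker count and
either scheduling strategy the output is identical, record-for-record, in
input-site order.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pysam

__all__ = [
    "GenomicSite",
    "ReadFilters",
    "PileupRecord",
    "SchedulingPlan",
    "count_bases_at_site",
    "run_pileup",
    "run_pileup_batch",
    "partition_sites",
    "PILEUP_COLUMNS",
]

BASES = ("A", "C", "G", "T")

PILEUP_COLUMNS = [
    "chrom", "pos", "rsid",
    "A", "C", "G", "T",
    "A_fwd", "A_rev", "C_fwd", "C_rev", "G_fwd", "G_rev", "T_fwd", "T_rev",
    "depth",
]


@dataclass(frozen=True)
class GenomicSite:
    """A single-nucleotide position, 1-based, optionally with alleles."""

    chrom: str
    pos: int  # 1-based
    rsid: Optional[str] = None
    ref: Optional[str] = None
    alt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref is not None and self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class ReadFilters:
    """Quality filters applied during base counting (mbq / mrq / mdc)."""

    min_base_quality: int = 0
    min_read_quality: int = 0
    min_depth: int = 1

    def __post_init__(self) -> None:
        if min(self.min_base_quality, self.min_read_quality, self.min_depth) < 0:
            raise ValueError("filters must be non-negative")


@dataclass
class PileupRecord:
    """Filtered base counts at one site, with per-strand breakdown."""

    site: GenomicSite
    counts: Mapping[str, int]
    strand_counts: Mapping[str, tuple[int, int]]  # base -> (fwd, rev)

    @property
    def depth(self) -> int:
        return sum(self.counts[b] for b in BASES)

    def count(self, base: Optional[str]) -> int:
        if base is None:
            return 0
        return int(self.counts.get(base.upper(), 0))

    def to_row(self) -> list:
        s = self.site
        row = [s.chrom, s.pos, s.rsid if s.rsid else "NA"]
        row += [self.counts[b] for b in BASES]
        for b in BASES:
            row += list(self.strand_counts[b])
        row.append(self.depth)
        return row


@dataclass(frozen=True)
class SchedulingPlan:
    """How to split a site list across worker threads.

    ``static`` pre-splits the list into one contiguous sublist per worker;
    ``dynamic`` has idle workers claim contiguous chunks of ``chunk_size``
    from a shared queue, which helps when per-site cost is very uneven
    (e.g. highly amplified regions).
    """

    strategy: str = "static"
    workers: int = 1
    chunk_size: int = 64

    def __post_init__(self) -> None:
        if self.strategy not in ("static", "dynamic"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


def _site_base_counts(
    aln: pysam.AlignmentFile,
    site: GenomicSite,
    filters: ReadFilters,
    include_flagged: bool,
    dedup_mates: bool,
) -> tuple[dict, dict]:
    if site.chrom not in aln.references:
        raise ValueError(f"contig {site.chrom!r} not present in alignment header")
    fwd = dict.fromkeys(BASES, 0)
    rev = dict.fromkeys(BASES, 0)
    seen_fragments: set[str] = set()
    target = site.pos - 1  # 0-based
    for read in aln.fetch(site.chrom, target, target + 1):
        if read.is_unmapped:
            continue
        if not include_flagged and (
            read.is_secondary or read.is_supplementary or read.is_duplicate
        ):
            continue
        if read.mapping_quality < filters.min_read_quality:
            continue
        if dedup_mates:
            if read.query_name in seen_fragments:
                continue
            seen_fragments.add(read.query_name)
        qpos = None
        for q, r in read.get_aligned_pairs(matches_only=True):
            if r == target:
                qpos = q
                break
        if qpos is None:  # deletion or reference skip spans the site
            continue
        quals = read.query_qualities
        if quals is not None and quals[qpos] < filters.min_base_quality:
            continue
        base = read.query_sequence[qpos].upper()
        if base not in fwd:  # N or other ambiguity codes
            continue
        (rev if read.is_reverse else fwd)[base] += 1
    return fwd, rev


def count_bases_at_site(
    alignment_source,
    site: GenomicSite,
    filters: ReadFilters = ReadFilters(),
    *,
    include_flagged: bool = False,
    dedup_mates: bool = False,
) -> PileupRecord:
    """Count filtered bases at a single 1-based position.

    ``alignment_source`` is a path to an indexed BAM or an open
    :class:`pysam.AlignmentFile`.
    """
    if isinstance(alignment_source, pysam.AlignmentFile):
        fwd, rev = _site_base_counts(alignment_source, site, filters,
                                     include_flagged, dedup_mates)
    else:
        with pysam.AlignmentFile(str(alignment_source), "rb") as aln:
            fwd, rev = _site_base_counts(aln, site, filters,
                                         include_flagged, dedup_mates)
    counts = {b: fwd[b] + rev[b] for b in BASES}
    strand = {b: (fwd[b], rev[b]) for b in BASES}
    return PileupRecord(site=site, counts=counts, strand_counts=strand)


def partition_sites(n_sites: int, plan: SchedulingPlan) -> list[list[range]]:
    """Assignment of site indices to workers, as contiguous index ranges.

    static: T contiguous sublists whose sizes differ by at most one, the
    earlier sublists taking the remainder. dynamic: contiguous chunks of
    ``chunk_size`` claimed in order by idle workers; returned here as the
    chunk sequence dealt round-robin (the runtime claim order is
    nondeterministic but the output contract does not depend on it).
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    T = plan.workers
    if plan.strategy == "static":
        base, extra = divmod(n_sites, T)
        out, start = [], 0
        for w in range(T):
            size = base + (1 if w < extra else 0)
            out.append([range(start, start + size)] if size else [])
            start += size
        return out
    chunks = [range(i, min(i + plan.chunk_size, n_sites))
              for i in range(0, n_sites, plan.chunk_size)]
    out = [[] for _ in range(T)]
    for i, chunk in enumerate(chunks):
        out[i % T].append(chunk)
    return out


def run_pileup(
    sites: Sequence[GenomicSite],
    alignment_source,
    filters: ReadFilters = ReadFilters(),
    plan: SchedulingPlan = SchedulingPlan(),
    *,
    include_flagged: bool = False,
    dedup_mates: bool = False,
) -> list[PileupRecord]:
    """Pile up every site, in input order, with a deterministic result.

    Each worker thread opens its own file handle (pysam handles are not
    thread-safe) and writes records into a pre-allocated slot per site, so
    the output is invariant to worker count and scheduling strategy. Any
    per-site error aborts the whole run; partial results are not emitted.
    """
    sites = list(sites)
    results: list[Optional[PileupRecord]] = [None] * len(sites)
    if not sites:
        return []
    path = str(alignment_source)
    plan_workers = min(plan.workers, len(sites))
    errors: list[Exception] = []

    if plan.strategy == "static":
        assignments = partition_sites(len(sites), SchedulingPlan("static", plan_workers))
        work_iters = [iter(chunks) for chunks in assignments]
    else:
        chunks = [range(i, min(i + plan.chunk_size, len(sites)))
                  for i in range(0, len(sites), plan.chunk_size)]
        queue_lock = threading.Lock()
        chunk_iter = iter(chunks)

        def claim():
            with queue_lock:
                return next(chunk_iter, None)

    def worker(worker_id: int) -> None:
        try:
            with pysam.AlignmentFile(path, "rb") as aln:
                if plan.strategy == "static":
                    my_chunks: Iterable[range] = assignments[worker_id]
                    for chunk in my_chunks:
                        for i in chunk:
                            fwd, rev = _site_base_counts(
                                aln, sites[i], filters, include_flagged, dedup_mates)
                            results[i] = PileupRecord(
                                site=sites[i],
                                counts={b: fwd[b] + rev[b] for b in BASES},
                                strand_counts={b: (fwd[b], rev[b]) for b in BASES})
                else:
                    while True:
                        chunk = claim()
                        if chunk is None:
                            return
                        for i in chunk:
                            fwd, rev = _site_base_counts(
                                aln, sites[i], filters, include_flagged, dedup_mates)
                            results[i] = PileupRecord(
                                site=sites[i],
                                counts={b: fwd[b] + rev[b] for b in BASES},
                                strand_counts={b: (fwd[b], rev[b]) for b in BASES})
        except Exception as exc:  # re-raised on the main thread with context
            errors.append(exc)

    if plan_workers == 1:
        worker(0)
    else:
        threads = [threading.Thread(target=worker, args=(w,))
                   for w in range(plan_workers)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
    if errors:
        raise RuntimeError(f"pileup failed: {errors[0]}") from errors[0]
    return results  # type: ignore[return-value]


@dataclass
class BatchJobResult:
    """Outcome of one job in a batch: records on success, error message on failure."""

    records: Optional[list[PileupRecord]] = None
    error: Optional[str] = None
    ok: bool = field(init=False)

    def __post_init__(self) -> None:
        self.ok = self.error is None


def run_pileup_batch(
    jobs: Sequence[tuple[Sequence[GenomicSite], object]],
    filters: ReadFilters = ReadFilters(),
    plan: SchedulingPlan = SchedulingPlan(),
    **kwargs,
) -> list[BatchJobResult]:
    """Run several (site list, alignment file) pileup jobs independently.

    A failing job records its error and does not abort the others.
    """
    out = []
    for job_sites, source in jobs:
        try:
            recs = run_pileup(job_sites, source, filters, plan, **kwargs)
            out.append(BatchJobResult(records=recs))
        except Exception as exc:
            out.append(BatchJobResult(error=str(exc)))
    return out
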