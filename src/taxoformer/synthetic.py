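"""Synthetic genomes, reads and mock communities for desk-scale experiments.

The generators emulate the study conditions the classifier was designed for:

* a two-level taxonomy (genera containing species) built by substituting a
  random root genome at a between-genus rate and each genus ancestor at a
  smaller within-genus rate;
* coverage-balanced training read sets: per-genome coverage
  ``C_i = round(L_max / L_i) * f`` so every class contributes roughly equal
  sequencing effort regardless of genome length (training uses f=3,
  validation f=1);
* 150 bp paired-end reads with insert size ~ Normal(400, 50) bp (truncated
  to feasible lengths) and iid substitution errors — a parametric stand-in
  for an empirical Illumina HiSeq2500 error profile (indels excluded; the
  classifier consumes base identities only);
* mock communities with abundances drawn log-normally (mu=1, sigma=2) and
  scaled to a fixed total read count M via largest-remainder rounding so the
  counts sum to M exactly.

All generators are deterministic given a seed (NumPy PCG64 streams).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .seqio import GenomeRecord, ReadRecord
from .tokenization import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CoverageSpec:
    """Per-genome coverages balancing sequencing effort across genome lengths."""

    lengths: Tuple[int, ...]
    factor: int
    coverages: Tuple[int, ...]


@dataclass
class CommunityProfile:
    """Mock-community abundances and the integer read counts they scale to."""

    members: List[str]
    abundances: np.ndarray
    total: int
    counts: np.ndarray

    def fractions(self) -> np.ndarray:
        return self.abundances / self.abundances.sum()


@dataclass
class SimTaxonomy:
    """A simulated genus/species taxonomy with one genome per species."""

    genera: List[str]
    species: List[Tuple[str, str]]  # (species id, genus id)
    genomes: List[GenomeRecord]  # one per species, labels {'genus','species'}
    d_between: float
    d_within: float


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability ``rate``.

    A substituted base becomes one of the 3 alternatives uniformly, so the
    observed per-site difference count is Binomial(L, rate) exactly.
    """
    out = codes.copy()
    hits = np.flatnonzero(rng.random(codes.shape[0]) < rate)
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size)
        out[hits] = (out[hits] + shift) % 4
    return out


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_taxonomy(
    n_genera: int,
    species_per_genus: int,
    genome_length: int,
    d_between: float,
    d_within: float,
    seed: int = 0,
) -> SimTaxonomy:
    """Simulate a genus/species genome set with controllable divergence.

    A root genome of iid uniform bases is substituted at rate ``d_between``
    to form each genus ancestor; each species genome is its genus ancestor
    substituted at rate ``d_within``.  Requires ``d_within < d_between``
    (otherwise genera are unlearnable).
    """
    if not (0 <= d_within < d_between <= 0.5):
        raise ValueError("require 0 <= d_within < d_between <= 0.5")
    if genome_length < 1000:
        raise ValueError("genome_length must be >= 1 kb")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=genome_length).astype(np.int8)
    genera, species, genomes = [], [], []
    for g in range(n_genera):
        gid = f"g{g:03d}"
        genera.append(gid)
        ancestor = _mutate(root, d_between, rng)
        for s in range(species_per_genus):
            sid = f"{gid}_s{s:02d}"
            codes = _mutate(ancestor, d_within, rng)
            species.append((sid, gid))
            genomes.append(
                GenomeRecord(
                    id=sid,
                    sequence=_codes_to_seq(codes),
                    labels={"genus": gid, "species": sid},
                )
            )
    return SimTaxonomy(
        genera=genera, species=species, genomes=genomes,
        d_between=d_between, d_within=d_within,
    )


def balanced_coverages(lengths: Sequence[int], f: int) -> CoverageSpec:
    """Per-genome coverage ``C_i = round(L_max / L_i) * f`` (ties to even).

    Shorter genomes receive proportionally higher coverage so every class
    contributes about ``f * L_max`` sequenced bases.
    """
    if len(lengths) == 0:
        raise ValueError("empty length list")
    if any(L <= 0 for L in lengths):
        raise ValueError("genome lengths must be positive")
    if f < 1 or int(f) != f:
        raise ValueError("coverage factor f must be a positive integer")
    lmax = max(lengths)
    # numpy round: nearest integer, ties to even
    cov = tuple(int(np.round(lmax / L)) * int(f) for L in lengths)
    return CoverageSpec(lengths=tuple(int(L) for L in lengths), factor=int(f), coverages=cov)


def _sample_truncated_normal(
    mu: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal(mu, sd) truncated to [lo, hi] by rejection (vectorised)."""
    out = np.empty(size)
    need = np.arange(size)
    while need.size:
        draw = rng.normal(mu, sd, size=need.size)
        good = (draw >= lo) & (draw <= hi)
        out[need[good]] = draw[good]
        need = need[~good]
        if sd <= 0:  # pragma: no cover - degenerate guard
            out[need] = np.clip(mu, lo, hi)
            break
    return out


def simulate_reads(
    genome: GenomeRecord,
    coverage: float,
    read_len: int = 150,
    paired: bool = True,
    insert_mu: float = 400.0,
    insert_sd: float = 50.0,
    err_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str = "",
) -> Iterator[ReadRecord]:
    """Simulate reads from one genome at the requested coverage.

    Paired mode: fragment starts are uniform, insert lengths are
    Normal(insert_mu, insert_sd) truncated to [read_len, |genome|]; mate 1 is
    the fragment start, mate 2 the reverse complement of the fragment end.
    Single-end mode emits forward-strand substrings.  Substitution errors hit
    each base independently at ``err_rate`` (uniform over the 3 alternatives).
    Fragment count is round(coverage * |genome| / (reads_per_fragment *
    read_len)).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    L = genome.length
    if read_len > L:
        raise ValueError(f"read_len {read_len} exceeds genome length {L}")
    rng = np.random.default_rng(seed)
    reads_per_fragment = 2 if paired else 1
    n_fragments = int(np.round(coverage * L / (reads_per_fragment * read_len)))
    codes = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    code_map = np.zeros(256, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code_map[ord(b)] = i
    codes = code_map[codes]
    prefix = id_prefix or genome.id
    labels = dict(genome.labels) if genome.labels else None

    if paired:
        inserts = np.round(
            _sample_truncated_normal(insert_mu, insert_sd, read_len, L, n_fragments, rng)
        ).astype(int)
        inserts = np.clip(inserts, read_len, L)
        starts = (rng.random(n_fragments) * (L - inserts + 1)).astype(int)
    else:
        inserts = np.full(n_fragments, read_len)
        starts = (rng.random(n_fragments) * (L - read_len + 1)).astype(int)

    for i in range(n_fragments):
        s, ins = int(starts[i]), int(inserts[i])
        r1 = codes[s : s + read_len]
        if err_rate > 0:
            r1 = _mutate(r1.astype(np.int8), err_rate, rng)
        seq1 = _codes_to_seq(np.asarray(r1, dtype=np.intp))
        if not paired:
            yield ReadRecord(
                id=f"{prefix}:f{i}", sequence=seq1, truth_labels=labels
            )
            continue
        end = codes[s + ins - read_len : s + ins]
        if err_rate > 0:
            end = _mutate(end.astype(np.int8), err_rate, rng)
        seq2 = revcomp(_codes_to_seq(np.asarray(end, dtype=np.intp)))
        yield ReadRecord(
            id=f"{prefix}:f{i}/1", sequence=seq1, mate=1, truth_labels=labels
        )
        yield ReadRecord(
            id=f"{prefix}:f{i}/2", sequence=seq2, mate=2, truth_labels=labels
        )


def generate_balanced_set(
    taxonomy: SimTaxonomy,
    f: int,
    read_len: int = 150,
    paired: bool = True,
    insert_mu: float = 400.0,
    insert_sd: float = 50.0,
    err_rate: float = 0.0,
    seed: int = 0,
    shuffle_buffer: int = 10000,
    id_namespace: str = "train",
) -> Tuple[List[ReadRecord], "object"]:
    """Coverage-balanced read set over all genomes of a taxonomy.

    Applies ``balanced_coverages`` then ``simulate_reads`` per genome and
    shuffles the pooled reads with a bounded buffer.  Returns the reads and a
    manifest DataFrame (read_id, species_id, genus_id).  Different seeds (and
    the ``id_namespace``) keep train/validation read ids disjoint.
    """
    import pandas as pd

    from ._murmur3 import murmur3_low64
    from .seqio import stream_batches

    if len(taxonomy.genomes) < 2:
        raise ValueError("taxonomy must contain at least 2 classes")
    spec = balanced_coverages([g.length for g in taxonomy.genomes], f)

    def all_reads():
        for genome, cov in zip(taxonomy.genomes, spec.coverages):
            gid_hash = murmur3_low64(genome.id.encode("ascii"), 0) % 2**31
            sub_seed = np.random.SeedSequence([seed, gid_hash]).generate_state(1)[0]
            yield from simulate_reads(
                genome, cov, read_len=read_len, paired=paired,
                insert_mu=insert_mu, insert_sd=insert_sd, err_rate=err_rate,
                seed=int(sub_seed), id_prefix=f"{id_namespace}:{genome.id}",
            )

    reads: List[ReadRecord] = []
    for batch in stream_batches(all_reads(), 1024, shuffle_buffer=shuffle_buffer, seed=seed):
        reads.extend(batch)
    manifest = pd.DataFrame(
        {
            "read_id": [r.id for r in reads],
            "species_id": [r.truth_labels["species"] for r in reads],
            "genus_id": [r.truth_labels["genus"] for r in reads],
        }
    )
    return reads, manifest


def mock_counts(abundances: Sequence[float], M: int) -> np.ndarray:
    """Integer read counts R_i = A_i / sum(A) * M via largest-remainder rounding.

    The counts sum to M exactly and each deviates from its exact share by
    less than one read.
    """
    A = np.asarray(abundances, dtype=float)
    if A.size == 0:
        raise ValueError("empty abundance vector")
    if (A < 0).any() or A.sum() <= 0:
        raise ValueError("abundances must be non-negative with a positive sum")
    if M < 0:
        raise ValueError("M must be non-negative")
    exact = A / A.sum() * M
    base = np.floor(exact).astype(np.int64)
    short = M - int(base.sum())
    if short > 0:
        remainders = exact - base
        # largest remainder first; ties broken by index order
        order = np.lexsort((np.arange(A.size), -remainders))
        base[order[:short]] += 1
    return base


def sample_lognormal_community(
    members: Sequence[str],
    M: int,
    mu: float = 1.0,
    sigma: float = 2.0,
    seed: int = 0,
    abundances: Optional[Sequence[float]] = None,
) -> CommunityProfile:
    """Mock community: abundances A_i = exp(Normal(mu, sigma)), counts via Eq.-style scaling.

    ``abundances`` overrides the draw (used for deterministic fixtures).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    if abundances is None:
        A = np.exp(rng.normal(mu, sigma, size=len(members)))
    else:
        A = np.asarray(abundances, dtype=float)
        if A.shape[0] != len(members):
            raise ValueError("abundances length must match members")
    counts = mock_counts(A, M)
    return CommunityProfile(members=list(members), abundances=A, total=int(M), counts=counts)
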