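"""Forward simulator of clonal diversification with mutation and import.

Emulates short-term clonal spread of an endosymbiont: a handful of founder
genotypes seed a sample of isolates; each isolate's lineage accumulates a
Poisson number of point mutations (one random site, one random base, at a
random locus) and a Poisson number of recombinational imports (wholesale
replacement of one locus's allele by a donor-pool allele at a fixed
nucleotide divergence from the founder's allele). Every event is logged, so
downstream estimates of the recombination:mutation ratio can be scored
against the realized truth.

Bookkeeping guarantees exact conservation: the number of sites at which an
isolate differs from its founder equals (imports × import divergence) +
mutations. To keep that exact, at most one import is applied per locus per
isolate, mutation sites are resampled if they would land where the isolate
already differs from its founder, and donor alleles differ from the founder
allele at disjoint, logged column sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignio import LocusAlignment

BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults describe a realistic small survey: four gene fragments of
    ~500 bp, two founder genotypes, 60 isolates, rare point mutation
    (0.05 expected events per lineage) and more frequent allele import
    (0.5 expected events per lineage) at 6 nt divergence per import.
    """

    n_loci: int = 4
    locus_length_bp: int = 500
    n_founders: int = 2
    n_isolates: int = 60
    mutation_events_mean: float = 0.05
    import_events_mean: float = 0.5
    import_divergence_nt: int = 6
    donor_pool_size: int = 8
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_loci, self.locus_length_bp, self.n_founders, self.n_isolates) < 1:
            raise SimConfigError("counts must be positive")
        if self.mutation_events_mean < 0 or self.import_events_mean < 0:
            raise SimConfigError("event means must be non-negative")
        if not (1 <= self.import_divergence_nt < self.locus_length_bp):
            raise SimConfigError(
                "import_divergence_nt must be in [1, locus_length_bp)"
            )
        if self.donor_pool_size < 1:
            raise SimConfigError("donor_pool_size must be positive")

    def to_keyvalue(self) -> str:
        return "".join(
            f"{k}={v}\n" for k, v in sorted(vars(self).items())
        )


@dataclass
class SimTruth:
    """Logged events and the realized import:mutation ratio."""

    events: list[dict] = field(default_factory=list)
    n_mutations: int = 0
    n_imports: int = 0

    @property
    def true_rm_ratio(self) -> float:
        if self.n_imports == 0:
            return 0.0
        if self.n_mutations == 0:
            return float("inf")
        return self.n_imports / self.n_mutations


@dataclass
class SimResult:
    config: SimConfig
    alignments: dict[str, LocusAlignment]
    metadata: list[dict]  # isolate_id, founder
    truth: SimTruth
    locus_order: list[str]


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def simulate(config: SimConfig) -> SimResult:
    """Run the forward simulation; fully reproducible under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    loci = [f"locus{i + 1}" for i in range(config.n_loci)]
    L = config.locus_length_bp

    # founder alleles per locus
    founder_seqs: dict[str, list[np.ndarray]] = {
        locus: [_random_seq(rng, L) for _ in range(config.n_founders)]
        for locus in loci
    }
    # donor pool per (locus, founder): alleles at exactly the configured
    # divergence from that founder allele, on distinct column sets
    donors: dict[tuple[str, int], list[tuple[np.ndarray, np.ndarray]]] = {}
    for locus in loci:
        for f in range(config.n_founders):
            pool = []
            used_colsets: set[frozenset[int]] = set()
            while len(pool) < config.donor_pool_size:
                cols = rng.choice(L, size=config.import_divergence_nt, replace=False)
                key = frozenset(cols.tolist())
                if key in used_colsets:
                    continue
                used_colsets.add(key)
                seq = founder_seqs[locus][f].copy()
                for c in cols:
                    choices = [b for b in "ACGT" if b != seq[c]]
                    seq[c] = choices[rng.integers(0, 3)]
                pool.append((seq, np.sort(cols)))
            donors[(locus, f)] = pool

    truth = SimTruth()
    metadata: list[dict] = []
    isolate_seqs: dict[str, list[np.ndarray]] = {locus: [] for locus in loci}
    isolate_ids: list[str] = []
    for i in range(config.n_isolates):
        iso = f"iso{i + 1:03d}"
        founder = int(rng.integers(0, config.n_founders))
        genome = {locus: founder_seqs[locus][founder].copy() for locus in loci}

        n_imp = int(rng.poisson(config.import_events_mean))
        n_imp = min(n_imp, config.n_loci)  # at most one import per locus
        imported_loci = list(rng.choice(config.n_loci, size=n_imp, replace=False))
        for locus_idx in imported_loci:
            locus = loci[locus_idx]
            donor_idx = int(rng.integers(0, config.donor_pool_size))
            donor_seq, donor_cols = donors[(locus, founder)][donor_idx]
            genome[locus] = donor_seq.copy()
            truth.events.append(
                {
                    "isolate_id": iso,
                    "event": "import",
                    "locus": locus,
                    "detail": f"donor{donor_idx + 1}",
                }
            )
            truth.n_imports += 1

        n_mut = int(rng.poisson(config.mutation_events_mean))
        for _ in range(n_mut):
            # resample until the site still matches the founder base, so
            # each mutation adds exactly one new difference
            while True:
                locus = loci[int(rng.integers(0, config.n_loci))]
                site = int(rng.integers(0, L))
                founder_base = founder_seqs[locus][founder][site]
                if genome[locus][site] != founder_base:
                    continue
                choices = [b for b in "ACGT" if b != founder_base]
                genome[locus][site] = choices[rng.integers(0, 3)]
                truth.events.append(
                    {
                        "isolate_id": iso,
                        "event": "mutation",
                        "locus": locus,
                        "detail": f"{founder_base}{site + 1}{genome[locus][site]}",
                    }
                )
                truth.n_mutations += 1
                break

        isolate_ids.append(iso)
        metadata.append({"isolate_id": iso, "founder": f"founder{founder + 1}"})
        for locus in loci:
            isolate_seqs[locus].append(genome[locus])

    alignments = {
        locus: LocusAlignment(
            locus_name=locus,
            isolate_ids=list(isolate_ids),
            sequences=["".join(s) for s in isolate_seqs[locus]],
        )
        for locus in loci
    }
    return SimResult(config, alignments, metadata, truth, loci)


def write_sim_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write per-locus FASTA, metadata TSV, truth-log TSV, and the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for locus, aln in result.alignments.items():
        p = outdir / f"{locus}.fasta"
        with open(p, "w") as fh:
            for iso, seq in zip(aln.isolate_ids, aln.sequences):
                fh.write(f">{iso}\n{seq}\n")
        paths[locus] = p
    meta = outdir / "metadata.tsv"
    with open(meta, "w") as fh:
        fh.write("isolate_id\tfounder\n")
        for row in result.metadata:
            fh.write(f"{row['isolate_id']}\t{row['founder']}\n")
    paths["metadata"] = meta
    truth = outdir / "truth.tsv"
    with open(truth, "w") as fh:
        fh.write("isolate_id\tevent\tlocus\tdetail\n")
        for ev in result.truth.events:
            fh.write(f"{ev['isolate_id']}\t{ev['event']}\t{ev['locus']}\t{ev['detail']}\n")
    paths["truth"] = truth
    cfg = outdir / "sim_config.txt"
    cfg.write_text(result.config.to_keyvalue())
    paths["config"] = cfg
    return paths
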