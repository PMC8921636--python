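"""Seeded synthetic spike-in experiments under the two-stage read model.

The generator emulates the calibration study design: a panel of spike-in
clonotypes at known frequency tiers (default nine tiers of five clones,
1e-6 to 5e-2, replicated six times) mixed into a long-tailed background
repertoire, sequenced to a fixed depth. Counts are drawn from the same
Poisson / gamma-mixed negative-binomial model the calculator evaluates, so
fitted parameters can be compared against known truth. Optional plants —
all-zero dropout clones, exclusive low-count false positives, and
index-hopping false positives at a fixed count ratio — exercise the
exclusion and false-positive pipelines end to end.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ModelParameterError
from .model import ReadModelParams, SamplingContext, SequencingContext
from .repertoire import STUDY_TIER_FREQS, ClonotypeRecord

__all__ = [
    "SpikeInDesign",
    "SimulatedExperiment",
    "simulate_read_counts",
    "generate_spikein_experiment",
    "write_experiment",
]

_BASES = np.array(list("ACGT"))


def default_tiers():
    """The study design: nine frequency tiers with five clones each."""
    return [(f, 5) for f in STUDY_TIER_FREQS]


@dataclass
class SpikeInDesign:
    """Layout of a synthetic spike-in experiment.

    ``tiers`` lists (sample frequency, clone count) pairs; the background is a
    discretized power-law repertoire filling the remaining frequency mass.
    """

    tiers: list = field(default_factory=default_tiers)
    n_replicates: int = 6
    chains: tuple = ("TRA", "TRB")
    background_clones: int = 1000
    background_exponent: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ModelParameterError("n_replicates must be >= 1")
        for freq, n in self.tiers:
            if not (0.0 < freq < 1.0) or n < 1:
                raise ModelParameterError(f"invalid tier ({freq}, {n})")
        if self.spike_mass > 1.0:
            raise ModelParameterError(
                f"tier frequencies sum to {self.spike_mass:.3g} > 1"
            )

    @property
    def spike_mass(self) -> float:
        return float(sum(f * n for f, n in self.tiers))

    @property
    def n_spikeins(self) -> int:
        return int(sum(n for _, n in self.tiers))


def _negbin_draws(rng: np.random.Generator, mu: np.ndarray, params: ReadModelParams) -> np.ndarray:
    """Sample read counts via the gamma-Poisson mixture matching the pmf."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if not np.any(pos):
        return out
    if params.eta == 0.0:
        out[pos] = rng.poisson(mu[pos])
        return out
    size = mu[pos] ** (2.0 - params.lam) / params.eta
    big = size > 1e12
    lam_mix = np.where(big, mu[pos], rng.gamma(np.where(big, 1.0, size)) * mu[pos] / np.where(big, 1.0, size))
    out[pos] = rng.poisson(lam_mix)
    return out


def simulate_read_counts(
    f_body: float,
    sctx: SamplingContext,
    rctx: SequencingContext,
    params: ReadModelParams,
    n_draws: int,
    seed: int,
) -> np.ndarray:
    """Draw read counts from the full two-stage model.

    For each draw the number of sampled target cells is Poisson with rate
    ``f_body * t_samp``, then the read count is negative binomial with mean
    ``(c_samp / t_samp) * r_e * t_read`` (pure Poisson when ``eta = 0``).
    Reproducible given ``seed``.
    """
    if not (0.0 <= f_body <= 1.0):
        raise ModelParameterError(f"f_body must be in [0, 1], got {f_body}")
    rng = np.random.default_rng(seed)
    c_samp = rng.poisson(f_body * sctx.t_samp, size=n_draws)
    mu = c_samp / sctx.t_samp * params.r_e * rctx.t_read
    return _negbin_draws(rng, mu, params)


def _random_cdr3s(rng: np.random.Generator, n: int, existing: set) -> list[str]:
    """Distinct random nucleotide CDR3s, length 24-60 in multiples of 3."""
    out = []
    while len(out) < n:
        length = int(rng.choice(np.arange(24, 61, 3)))
        seq = "".join(rng.choice(_BASES, size=length))
        if seq not in existing:
            existing.add(seq)
            out.append(seq)
    return out


@dataclass
class SimulatedExperiment:
    """A generated spike-in experiment with its ground truth.

    ``reference`` is the spike-in reference frame (clone_id, chain,
    cdr3_nt_imgt, design_freq); ``tables`` maps (chain, replicate_id) to a
    MiXCR-dialect clonotype frame; ``records`` flattens the tables into
    :class:`~tcrdetect.repertoire.ClonotypeRecord` lists keyed the same way.
    """

    reference: pd.DataFrame
    tables: dict
    set_id: str
    t_read: int
    dropout_clone_ids: list = field(default_factory=list)
    fp_exclusive: list = field(default_factory=list)
    fp_hopping: list = field(default_factory=list)

    def records(self, chain: str, replicate_id: str) -> list[ClonotypeRecord]:
        df = self.tables[(chain, replicate_id)]
        return [
            ClonotypeRecord(row.nSeqCDR3, chain, int(row.cloneCount),
                            float(row.cloneFraction), self.set_id, replicate_id)
            for row in df.itertuples(index=False)
        ]

    def all_records(self) -> list[ClonotypeRecord]:
        out = []
        for chain, rep in sorted(self.tables):
            out.extend(self.records(chain, rep))
        return out

    def calibration_observations(self, chain: str):
        """Spike-in observations (known f_samp, observed count) per replicate."""
        from .calibration import CalibrationObservation

        ref = self.reference[self.reference["chain"] == chain]
        obs = []
        for (ch, rep), df in sorted(self.tables.items()):
            if ch != chain:
                continue
            counts = dict(zip(df["nSeqCDR3"], df["cloneCount"]))
            for row in ref.itertuples(index=False):
                obs.append(CalibrationObservation(
                    f_samp=float(row.design_freq),
                    c_read=int(counts.get(row.cdr3_nt_imgt, 0)),
                    chain=chain, set_id=self.set_id, replicate_id=rep,
                ))
        return obs


def generate_spikein_experiment(
    design: SpikeInDesign,
    params: ReadModelParams,
    t_read: int,
    set_id: str = "Set1",
    two_step: bool = False,
    t_samp: int | None = None,
    n_dropouts: int = 0,
    dropout_chains: tuple = ("TRA", "TRB"),
    fp_exclusive_counts=None,
    hop_sources=None,
    hop_ratio: float = 0.01,
    exact_totals: bool = False,
) -> SimulatedExperiment:
    """Generate a full synthetic spike-in experiment.

    By default counts come from the read model alone (the spike-in frequency
    is a known in-sample quantity, as in the calibration experiments); with
    ``two_step=True`` a Poisson sampling stage of ``t_samp`` cells is applied
    first. Dropout clones are zeroed in every replicate of the listed chains.
    ``fp_exclusive_counts`` plants that many exclusive false positives with
    the given read counts; ``hop_sources`` is an iterable of (chain, cdr3,
    source_count) planted at ``max(1, round(hop_ratio * source_count))``
    reads, emulating index hopping. ``exact_totals`` rescales each replicate
    to exactly ``t_read`` reads by a multinomial redraw.
    """
    if two_step and t_samp is None:
        raise ModelParameterError("two_step generation requires t_samp")
    rng = np.random.default_rng(design.seed)
    existing: set = set()

    # Reference panel: same clone ids across chains, distinct CDR3s per chain.
    freqs = []
    for tier_freq, n in design.tiers:
        freqs.extend([tier_freq] * n)
    clone_ids = [f"TCC{i + 1:03d}" for i in range(len(freqs))]
    ref_rows = []
    chain_cdr3s = {}
    for chain in design.chains:
        cdr3s = _random_cdr3s(rng, len(freqs), existing)
        chain_cdr3s[chain] = cdr3s
        for cid, cdr3, fv in zip(clone_ids, cdr3s, freqs):
            ref_rows.append({"clone_id": cid, "chain": chain,
                             "cdr3_nt_imgt": cdr3, "design_freq": fv})
    reference = pd.DataFrame(ref_rows)

    dropout_ids = list(clone_ids[-n_dropouts:]) if n_dropouts else []

    # Background repertoire: discretized power law over the leftover mass.
    bg_mass = max(0.0, 1.0 - design.spike_mass)
    bg = {}
    for chain in design.chains:
        if design.background_clones > 0 and bg_mass > 0:
            ranks = np.arange(1, design.background_clones + 1, dtype=float)
            w = ranks ** -design.background_exponent
            bg_freqs = bg_mass * w / w.sum()
            bg_cdr3s = _random_cdr3s(rng, design.background_clones, existing)
            bg[chain] = (bg_cdr3s, bg_freqs)
        else:
            bg[chain] = ([], np.array([]))

    fp_exclusive = []
    if fp_exclusive_counts is not None:
        for chain in design.chains:
            cdr3s = _random_cdr3s(rng, len(fp_exclusive_counts), existing)
            for cdr3, count in zip(cdr3s, fp_exclusive_counts):
                fp_exclusive.append((chain, cdr3, int(count)))
    fp_hopping = []
    if hop_sources:
        for chain, cdr3, src_count in hop_sources:
            fp_hopping.append((chain, cdr3, max(1, round(hop_ratio * src_count))))

    tables = {}
    for chain in design.chains:
        spike_cdr3 = chain_cdr3s[chain]
        bg_cdr3, bg_freqs = bg[chain]
        all_cdr3 = np.array(spike_cdr3 + bg_cdr3)
        all_freq = np.concatenate([np.array(freqs), bg_freqs])
        drop_mask = np.zeros(all_cdr3.size, dtype=bool)
        if dropout_ids and chain in dropout_chains:
            drop_idx = [clone_ids.index(cid) for cid in dropout_ids]
            drop_mask[drop_idx] = True

        for rep in range(1, design.n_replicates + 1):
            if two_step:
                c_samp = rng.poisson(all_freq * t_samp)
                mu = c_samp / t_samp * params.r_e * t_read
            else:
                mu = all_freq * params.r_e * t_read
            counts = _negbin_draws(rng, mu, params)
            counts[drop_mask] = 0
            cdr3s = list(all_cdr3)
            counts = list(counts)
            for fp_chain, cdr3, count in fp_exclusive + fp_hopping:
                if fp_chain == chain:
                    cdr3s.append(cdr3)
                    counts.append(count)
            counts = np.array(counts, dtype=np.int64)
            if exact_totals and counts.sum() > 0:
                counts = rng.multinomial(t_read, counts / counts.sum())
            total = counts.sum()
            tables[(chain, str(rep))] = pd.DataFrame({
                "cloneCount": counts,
                "cloneFraction": counts / total if total else 0.0,
                "nSeqCDR3": cdr3s,
            })

    return SimulatedExperiment(
        reference=reference, tables=tables, set_id=set_id, t_read=int(t_read),
        dropout_clone_ids=dropout_ids, fp_exclusive=fp_exclusive,
        fp_hopping=fp_hopping,
    )


def write_experiment(exp: SimulatedExperiment, outdir) -> dict:
    """Write reference and per-replicate clonotype tables; return checksums.

    File contents are deterministic given the generator seed, so the returned
    ``{filename: sha256}`` manifest is reproducible byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}

    def write(df, name):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    write(exp.reference, "spikein_reference.tsv")
    for (chain, rep), df in sorted(exp.tables.items()):
        write(df, f"{exp.set_id}_{chain}_rep{rep}.tsv")
    return manifest
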