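"""Synthetic study generator: reference genome, tumor cohort, clone pairs.

Generates a complete synthetic dataset with the statistical structure the
analysis assumes, so every pipeline stage can be exercised and validated
without any external download:

* a random reference genome (uniform base composition), written as indexed
  FASTA;
* a cohort of tumors whose somatic catalogs are drawn from mixtures of
  pseudo-signatures — samples flagged with MUTYH or OGG1 copy-number loss
  receive C>A-heavy mixtures (total C>A mass ≈ 0.55 versus ≈ 0.27 for
  wild-type-like samples), CBS scores drawn from a loss or neutral
  distribution, and right-censored survival times whose exponential hazard
  increases with the true C>A fraction;
* clone/subclone pairs where the subclone is a superset of the clone, with
  variants accrued at a genotype-specific per-day rate over a culture period
  drawn from 88–126 days.

Every generated variant is placed at a genome position whose reference
context matches its channel, so spectra recomputed from the reference agree
with the generating mixture.  A truth table records every generating
parameter per sample.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clonal import ClonalPair
from .signatures import SignatureMatrix
from .spectra import BASES, CHANNELS_96, SUB_CLASSES
from .variant_io import (
    GeneCBSRecord,
    MutationCatalog,
    ReferenceContextSource,
    SurvivalRecord,
    write_snv_vcf,
)

# pyrimidine alt base code per substitution class (A=0,C=1,G=2,T=3)
_ALT_CODE = np.array([0, 2, 3, 0, 1, 2])
_REF_CODE = np.array([1, 1, 1, 3, 3, 3])


# ---------------------------------------------------------------------------
# reference genome


def make_reference(
    path: str | Path, n_chroms: int = 2, length: int = 500_000, seed: int = 0
) -> Path:
    """Write a random uniform-composition genome as FASTA (deterministic per seed)."""
    if length < 3:
        raise ValueError("chromosome length must be at least 3")
    rng = np.random.default_rng(seed)
    path = Path(path)
    with open(path, "w") as fh:
        for i in range(1, n_chroms + 1):
            seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
            fh.write(f">{i}\n")
            for j in range(0, length, 70):
                fh.write(seq[j : j + 70] + "\n")
    return path


class ContextIndex:
    """Genome positions grouped by trinucleotide context, for mutation placement."""

    def __init__(self, reference: ReferenceContextSource):
        self.reference = reference
        chrom_ids, positions, ctx = [], [], []
        self.chrom_names = sorted(reference._names)
        for ci, chrom in enumerate(self.chrom_names):
            codes = reference._chrom_codes(chrom)
            if len(codes) < 3:
                continue
            l, m, r = codes[:-2], codes[1:-1], codes[2:]
            ok = (l < 4) & (m < 4) & (r < 4)
            pos = np.flatnonzero(ok) + 2  # 1-based position of middle base
            chrom_ids.append(np.full(len(pos), ci, dtype=np.int32))
            positions.append(pos.astype(np.int64))
            ctx.append((16 * l + 4 * m + r)[ok])
        self.chrom_id = np.concatenate(chrom_ids)
        self.pos = np.concatenate(positions)
        ctx_all = np.concatenate(ctx)
        order = np.argsort(ctx_all, kind="stable")
        self.chrom_id = self.chrom_id[order]
        self.pos = self.pos[order]
        self._bounds = np.searchsorted(ctx_all[order], np.arange(65))

    def positions_for(self, ctx_id: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self._bounds[ctx_id], self._bounds[ctx_id + 1]
        return self.chrom_id[lo:hi], self.pos[lo:hi]


def _channel_sites(channel_idx: int) -> tuple[int, int, int, int]:
    """(fwd ctx id, rev ctx id, fwd alt code, rev alt code) for one channel."""
    sub, rest = divmod(channel_idx, 16)
    five, three = divmod(rest, 4)
    ref = _REF_CODE[sub]
    alt = _ALT_CODE[sub]
    fwd = 16 * five + 4 * ref + three
    rev = 16 * (3 - three) + 4 * (3 - ref) + (3 - five)
    return fwd, rev, int(alt), int(3 - alt)


class UnsatisfiableChannelError(RuntimeError):
    """No genome position carries the context a channel requires."""


def place_channel_draws(
    channel_ids: np.ndarray, index: ContextIndex, rng: np.random.Generator
) -> pd.DataFrame:
    """Place sampled channels at uniformly chosen context-matching positions.

    Positions are drawn uniformly (with replacement) among all genome sites
    whose forward- or reverse-strand context matches the channel; duplicate
    (chrom, pos, alt) draws are collapsed downstream by catalog
    deduplication.
    """
    counts = np.bincount(channel_ids, minlength=96)
    chroms, positions, refs, alts = [], [], [], []
    base = np.array(list(BASES))
    for ch in np.flatnonzero(counts):
        fwd, rev, alt_f, alt_r = _channel_sites(int(ch))
        cf, pf = index.positions_for(fwd)
        cr, pr = index.positions_for(rev)
        total = len(pf) + len(pr)
        if total == 0:
            raise UnsatisfiableChannelError(
                f"no genome site matches channel {CHANNELS_96[ch]!r}"
            )
        draw = rng.integers(0, total, size=int(counts[ch]))
        on_fwd = draw < len(pf)
        i_f = draw[on_fwd]
        i_r = draw[~on_fwd] - len(pf)
        sub = ch // 16
        ref_f = base[_REF_CODE[sub]]
        ref_r = base[3 - _REF_CODE[sub]]
        for ci, pi, rb, ab in (
            (cf[i_f], pf[i_f], ref_f, base[alt_f]),
            (cr[i_r], pr[i_r], ref_r, base[alt_r]),
        ):
            if len(pi):
                chroms.append(np.array(index.chrom_names)[ci])
                positions.append(pi)
                refs.append(np.full(len(pi), rb))
                alts.append(np.full(len(pi), ab))
    if not positions:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    return pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "pos": np.concatenate(positions),
            "ref": np.concatenate(refs),
            "alt": np.concatenate(alts),
        }
    )


# ---------------------------------------------------------------------------
# pseudo-signatures

_CA_MASS = {"PS1": 0.02, "PS5": 0.08, "PS18": 0.85, "PS36": 0.85, "PS40": 0.15}


def pseudo_signature_matrix() -> SignatureMatrix:
    """Five distinguishable synthetic signatures in COSMIC 96-channel layout.

    PS18 and PS36 are C>A-dominant (0.85 of their mass in the C>A block, with
    different context profiles) and stand in for the oxidative-damage
    signatures SBS18/SBS36; PS1 is CpG-deamination-like (C>T at NpCpG), PS5 a
    broad T>C profile, PS40 a flat background.  This is a synthetic fixture,
    not the COSMIC catalog; real COSMIC files load through the same reader.
    """
    cols = {}

    def block(sub: str) -> slice:
        i = SUB_CLASSES.index(sub)
        return slice(16 * i, 16 * (i + 1))

    # PS18: C>A heavy, peaked on a 3'-T / 3'-A decaying profile
    v = np.zeros(96)
    profile = np.array([3.0, 1.0, 0.5, 4.0] * 4) * np.array(
        [1.5] * 4 + [1.0] * 4 + [2.0] * 4 + [3.0] * 4
    )
    v[block("C>A")] = 0.85 * profile / profile.sum()
    rest = np.ones(96)
    rest[block("C>A")] = 0
    v += 0.15 * rest / rest.sum()
    cols["PS18"] = v

    # PS36: C>A heavy, peaked on 5'-A/5'-C contexts instead
    v = np.zeros(96)
    profile = np.array([4.0] * 4 + [3.0] * 4 + [0.5] * 4 + [1.0] * 4) * np.array(
        [2.0, 1.0, 1.0, 0.5] * 4
    )
    v[block("C>A")] = 0.85 * profile / profile.sum()
    rest = np.ones(96)
    rest[block("C>A")] = 0
    v += 0.15 * rest / rest.sum()
    cols["PS36"] = v

    # PS1: C>T at XpCpG contexts (3' base G), tiny flat remainder
    v = np.zeros(96)
    ct = np.zeros(16)
    ct[[2, 6, 10, 14]] = 1.0  # A[C>T]G, C[C>T]G, G[C>T]G, T[C>T]G
    v[block("C>T")] = 0.88 * ct / ct.sum()
    v[block("C>A")] = 0.02 / 16
    rest = np.ones(96)
    rest[block("C>T")] = 0
    rest[block("C>A")] = 0
    v += 0.10 * rest / rest.sum()
    cols["PS1"] = v

    # PS5: broad T>C with moderate background
    v = np.zeros(96)
    v[block("T>C")] = 0.60 / 16
    v[block("C>A")] = 0.08 / 16
    rest = np.ones(96)
    rest[block("T>C")] = 0
    rest[block("C>A")] = 0
    v += 0.32 * rest / rest.sum()
    cols["PS5"] = v

    # PS40: flat background with a mild C>A component
    v = np.zeros(96)
    v[block("C>A")] = 0.15 / 16
    rest = np.ones(96)
    rest[block("C>A")] = 0
    v += 0.85 * rest / rest.sum()
    cols["PS40"] = v

    names = ["PS1", "PS5", "PS18", "PS36", "PS40"]
    P = np.column_stack([cols[n] / cols[n].sum() for n in names])
    return SignatureMatrix(names=names, P=P)


#: Default per-group signature mixtures.  C>A mass of the mixture works out to
#: ≈0.27 for WT and ≈0.55 for the CNL groups (weights x per-signature C>A mass).
#: Tumor-cohort loss groups are PS18-led — in heterozygous-loss tumors the
#: oxidative C>A burden is SBS18-like, with a strong SBS36-like component
#: essentially confined to biallelic MUTYH inactivation — so MUTYH-CNL tumors
#: carry PS36 only as a secondary component, unlike the biallelic knockout
#: clones below.
GROUP_WEIGHTS = {
    "WT": {"PS18": 0.25, "PS1": 0.30, "PS5": 0.27, "PS40": 0.18},
    "MUTYH_CNL": {"PS18": 0.45, "PS36": 0.17, "PS1": 0.15, "PS5": 0.13, "PS40": 0.10},
    "OGG1_CNL": {"PS18": 0.62, "PS1": 0.15, "PS5": 0.13, "PS40": 0.10},
    "BOTH": {"PS18": 0.45, "PS36": 0.17, "PS1": 0.15, "PS5": 0.13, "PS40": 0.10},
}

#: Clone-experiment mixtures: knockout of either glycosylase pushes the C>A
#: mass to ≈0.50; the nucleotide-pool sanitizer knockout behaves like WT.
CLONE_WEIGHTS = {
    "WT": {"PS18": 0.25, "PS1": 0.30, "PS5": 0.27, "PS40": 0.18},
    "NUDT1_KO": {"PS18": 0.25, "PS1": 0.30, "PS5": 0.27, "PS40": 0.18},
    "OGG1_KO": {"PS18": 0.55, "PS1": 0.18, "PS5": 0.15, "PS40": 0.12},
    "MUTYH_KO": {"PS36": 0.55, "PS1": 0.18, "PS5": 0.15, "PS40": 0.12},
}


def mixture_channel_probs(weights: dict[str, float], matrix: SignatureMatrix) -> np.ndarray:
    w = np.array([weights.get(n, 0.0) for n in matrix.names])
    if not np.isclose(w.sum(), 1.0):
        raise ValueError(f"mixture weights sum to {w.sum():.4f}, not 1")
    return matrix.P @ w


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortSpec:
    """Generating parameters of the synthetic tumor cohort."""

    n_samples: int = 86
    group_weights: dict = field(default_factory=lambda: dict(GROUP_WEIGHTS))
    mutations_median: float = 2000.0
    mutations_sigma: float = 0.5
    frac_mutyh_cnl: float = 0.15
    frac_ogg1_cnl: float = 0.25
    frac_both: float = 0.02
    cbs_loss_mean: float = -0.8
    cbs_loss_sd: float = 0.15
    cbs_neutral_mean: float = 0.0
    cbs_neutral_sd: float = 0.1
    survival_h0: float = 0.002  #: baseline hazard per month
    survival_beta: float = 6.0  #: log hazard ratio per unit C>A fraction
    censor_low: float = 24.0  #: administrative censoring window (months)
    censor_high: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.frac_mutyh_cnl, self.frac_ogg1_cnl, self.frac_both):
            if not 0 <= frac <= 1:
                raise ValueError("group fractions must lie in [0, 1]")
        if self.frac_mutyh_cnl + self.frac_ogg1_cnl + self.frac_both > 1:
            raise ValueError("group fractions exceed 1")


@dataclass
class SyntheticCohort:
    catalogs: list[MutationCatalog]
    cbs_records: list[GeneCBSRecord]
    survival_records: list[SurvivalRecord]
    truth: pd.DataFrame
    matrix: SignatureMatrix


def simulate_survival_times(
    ca_fractions: np.ndarray,
    rng: np.random.Generator,
    h0: float = 0.002,
    beta: float = 6.0,
    censor_low: float = 24.0,
    censor_high: float = 120.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival with hazard h0·exp(beta·fraction) and uniform
    administrative censoring; returns (time, event)."""
    lam = h0 * np.exp(beta * np.asarray(ca_fractions, dtype=float))
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.uniform(censor_low, censor_high, size=len(lam))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return time, event


def simulate_cohort(
    spec: CohortSpec,
    reference: ReferenceContextSource,
    matrix: SignatureMatrix | None = None,
    place_variants: bool = True,
) -> SyntheticCohort:
    """Draw a full synthetic cohort: catalogs, CBS table, clinical table, truth.

    Each tumor's mutations are drawn channel-by-channel from its group's
    signature mixture and placed at context-matching genome positions.  With
    ``place_variants=False`` the catalogs are empty and only the truth table
    (including exact sampled channel counts) is produced — useful for
    survival-only simulations.
    """
    rng = np.random.default_rng(spec.seed)
    matrix = matrix or pseudo_signature_matrix()
    index = ContextIndex(reference) if place_variants else None

    probs = {g: mixture_channel_probs(w, matrix) for g, w in spec.group_weights.items()}
    group_names = ["MUTYH_CNL", "OGG1_CNL", "BOTH", "WT"]
    group_p = [
        spec.frac_mutyh_cnl,
        spec.frac_ogg1_cnl,
        spec.frac_both,
        1 - spec.frac_mutyh_cnl - spec.frac_ogg1_cnl - spec.frac_both,
    ]
    groups = rng.choice(group_names, size=spec.n_samples, p=group_p)

    catalogs, cbs_records, rows = [], [], []
    mu = np.log(spec.mutations_median)
    n_muts = np.maximum(
        50, rng.lognormal(mu, spec.mutations_sigma, size=spec.n_samples).astype(int)
    )
    ca_true = np.zeros(spec.n_samples)
    for i in range(spec.n_samples):
        sample_id = f"S{i + 1:03d}"
        group = str(groups[i])
        channel_ids = rng.choice(96, size=int(n_muts[i]), p=probs[group])
        ca_true[i] = float((channel_ids < 16).mean())
        if place_variants:
            df = place_channel_draws(channel_ids, index, rng)
            catalogs.append(MutationCatalog(sample_id, df, n_indels=int(rng.poisson(40))))
        else:
            catalogs.append(MutationCatalog(sample_id))

        loss_mutyh = group in ("MUTYH_CNL", "BOTH")
        loss_ogg1 = group in ("OGG1_CNL", "BOTH")
        for gene, lost in (("MUTYH", loss_mutyh), ("OGG1", loss_ogg1), ("NUDT1", False)):
            if lost:
                cbs = rng.normal(spec.cbs_loss_mean, spec.cbs_loss_sd)
                cbs = min(cbs, -0.51)  # a generated loss is a true loss
            else:
                cbs = rng.normal(spec.cbs_neutral_mean, spec.cbs_neutral_sd)
                cbs = max(cbs, -0.49)
            cbs_records.append(GeneCBSRecord(sample_id, gene, float(cbs)))

        rows.append(
            {
                "sample_id": sample_id,
                "group": group,
                "n_mutations": int(n_muts[i]),
                "ca_fraction_true": ca_true[i],
            }
        )

    time, event = simulate_survival_times(
        ca_true,
        rng,
        h0=spec.survival_h0,
        beta=spec.survival_beta,
        censor_low=spec.censor_low,
        censor_high=spec.censor_high,
    )
    survival_records = []
    for i, row in enumerate(rows):
        stage = int(rng.choice([4, 3, 2, 1], p=[0.6, 0.2, 0.1, 0.1])) if ca_true[i] > 0.4 else int(
            rng.choice([4, 3, 2, 1], p=[0.2, 0.2, 0.3, 0.3])
        )
        mycn = int(rng.random() < 0.2)
        row.update(time=float(time[i]), event=int(event[i]), inss_stage=stage, mycn=mycn)
        survival_records.append(
            SurvivalRecord(
                row["sample_id"],
                float(time[i]),
                int(event[i]),
                {
                    "ca_fraction": ca_true[i],
                    "inss_stage": stage,
                    "mycn": mycn,
                },
            )
        )

    truth = pd.DataFrame(rows)
    return SyntheticCohort(catalogs, cbs_records, survival_records, truth, matrix)


# ---------------------------------------------------------------------------
# clone/subclone pairs


@dataclass
class CloneSpec:
    """Generating parameters of the knockout clone-expansion experiment."""

    genotype_weights: dict = field(default_factory=lambda: dict(CLONE_WEIGHTS))
    accrual_rates: dict = field(
        default_factory=lambda: {
            "WT": 1.0,
            "NUDT1_KO": 1.0,
            "OGG1_KO": 2.5,
            "MUTYH_KO": 2.5,
        }
    )  #: substitutions per genome per day
    days_low: float = 88.0
    days_high: float = 126.0
    replicates: int = 2
    clone_background: float = 1000.0  #: expected pre-existing clone mutations
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.days_low <= self.days_high:
            raise ValueError("culture-duration range must be positive")
        if any(r <= 0 for r in self.accrual_rates.values()):
            raise ValueError("accrual rates must be positive")


def simulate_clonal_pairs(
    spec: CloneSpec,
    reference: ReferenceContextSource,
    matrix: SignatureMatrix | None = None,
) -> tuple[list[ClonalPair], pd.DataFrame]:
    """Simulate clone/subclone pairs; subclone = clone ∪ Poisson(rate·days) accrual."""
    rng = np.random.default_rng(spec.seed)
    matrix = matrix or pseudo_signature_matrix()
    index = ContextIndex(reference)
    background_probs = mixture_channel_probs(spec.genotype_weights["WT"], matrix)

    pairs, rows = [], []
    for genotype in spec.genotype_weights:
        probs = mixture_channel_probs(spec.genotype_weights[genotype], matrix)
        for rep in range(1, spec.replicates + 1):
            days = float(rng.uniform(spec.days_low, spec.days_high))
            n_bg = int(rng.poisson(spec.clone_background))
            bg_channels = rng.choice(96, size=n_bg, p=background_probs)
            clone_df = place_channel_draws(bg_channels, index, rng)
            clone_indels = int(rng.poisson(50))
            clone = MutationCatalog(f"{genotype}_c{rep}", clone_df, clone_indels)

            n_accrued = int(rng.poisson(spec.accrual_rates[genotype] * days))
            acc_channels = rng.choice(96, size=n_accrued, p=probs)
            acc_df = place_channel_draws(acc_channels, index, rng)
            sub_df = pd.concat([clone.df, acc_df], ignore_index=True)
            subclone = MutationCatalog(
                f"{genotype}_s{rep}", sub_df, clone_indels + int(rng.poisson(5))
            )
            pairs.append(ClonalPair(clone, subclone, days, genotype))
            rows.append(
                {
                    "pair_id": subclone.sample_id,
                    "genotype": genotype,
                    "days": days,
                    "n_background": n_bg,
                    "n_accrued_drawn": n_accrued,
                    "ca_fraction_drawn": float((acc_channels < 16).mean())
                    if n_accrued
                    else 0.0,
                    "rate_true": spec.accrual_rates[genotype],
                }
            )
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file output


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as per-sample VCFs plus CBS/clinical/truth tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_dir = out_dir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for cat in cohort.catalogs:
        write_snv_vcf(cat, vcf_dir / f"{cat.sample_id}.vcf")
    cbs = pd.DataFrame(
        [(r.sample_id, r.gene, r.cbs) for r in cohort.cbs_records],
        columns=["sample_id", "gene", "cbs"],
    )
    cbs.to_csv(out_dir / "cbs.tsv", sep="\t", index=False)
    clin = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "time": r.time,
                "event": r.event,
                **r.covariates,
            }
            for r in cohort.survival_records
        ]
    )
    clin.to_csv(out_dir / "clinical.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return {
        "vcf_dir": vcf_dir,
        "cbs": out_dir / "cbs.tsv",
        "clinical": out_dir / "clinical.tsv",
        "truth": out_dir / "truth.tsv",
    }


def write_clonal(pairs: list[ClonalPair], truth: pd.DataFrame, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = []
    for pair in pairs:
        write_snv_vcf(pair.clone, out_dir / f"{pair.clone.sample_id}.vcf")
        write_snv_vcf(pair.subclone, out_dir / f"{pair.subclone.sample_id}.vcf")
        meta.append(
            {
                "clone": pair.clone.sample_id,
                "subclone": pair.subclone.sample_id,
                "days": pair.days,
                "genotype": pair.genotype,
            }
        )
    pd.DataFrame(meta).to_csv(out_dir / "pairs.tsv", sep="\t", index=False)
    truth.to_csv(out_dir / "clone_truth.tsv", sep="\t", index=False)
    return out_dir
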