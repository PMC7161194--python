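"""Genotype and allele-frequency containers, file I/O, and marker QC.

Dosages count the ALT allele (0, 1, 2) and missingness is encoded as NaN;
frequency tables store ALT-allele frequencies. This single convention is
applied everywhere so that no strand/allele-flip ambiguity can arise
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AUTOSOMES = {str(c) for c in range(1, 23)}

MARKER_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt"]


class PopdataError(ValueError):
    """Raised on malformed input files or contract violations."""


def _validate_markers(markers: pd.DataFrame) -> pd.DataFrame:
    markers = markers.reset_index(drop=True)
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise PopdataError(f"marker table lacks columns: {missing}")
    if markers["marker_id"].duplicated().any():
        dups = markers.loc[markers["marker_id"].duplicated(), "marker_id"].tolist()
        raise PopdataError(f"duplicate marker IDs: {dups[:5]}")
    markers = markers.copy()
    markers["chrom"] = markers["chrom"].astype(str)
    markers["pos"] = markers["pos"].astype(np.int64)
    if (markers["pos"] < 1).any():
        raise PopdataError("positions must be >= 1 (1-based coordinates)")
    same = markers["ref"].astype(str) == markers["alt"].astype(str)
    if same.any():
        raise PopdataError("ref and alt alleles must differ")
    return markers


@dataclass
class GenotypeMatrix:
    """Individuals x markers ALT-allele dosage matrix.

    Parameters
    ----------
    dosages : ndarray, shape (n_samples, n_markers)
        Float array with entries in {0, 1, 2} and NaN for missing calls.
    markers : DataFrame
        One row per marker with columns marker_id, chrom, pos, ref, alt.
    samples : list of str
        Unique sample identifiers, one per dosage row.
    labels : dict, optional
        Map sample -> population name for labelled (reference) samples.
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    samples: list[str]
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.markers = _validate_markers(self.markers)
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise PopdataError("duplicate sample IDs")
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.markers):
            raise PopdataError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise PopdataError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["marker_id"].tolist()

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        """Restrict to the given markers, in the given order."""
        idx = pd.Index(self.markers["marker_id"])
        pos = idx.get_indexer(list(marker_ids))
        if (pos < 0).any():
            missing = [m for m, p in zip(marker_ids, pos) if p < 0]
            raise PopdataError(f"markers not present: {missing[:5]}")
        return GenotypeMatrix(
            self.dosages[:, pos],
            self.markers.iloc[pos].reset_index(drop=True),
            self.samples,
            self.labels,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            rows = [lookup[s] for s in sample_ids]
        except KeyError as exc:
            raise PopdataError(f"sample not present: {exc}") from exc
        return GenotypeMatrix(
            self.dosages[rows, :], self.markers, list(sample_ids), self.labels
        )


@dataclass
class FrequencyTable:
    """Populations x markers table of ALT-allele frequencies.

    NaN marks a frequency that could not be estimated (no calls in that
    population); such markers are flagged by downstream consumers rather
    than imputed.
    """

    freqs: np.ndarray
    markers: pd.DataFrame
    populations: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.markers = _validate_markers(self.markers)
        self.populations = list(self.populations)
        if self.freqs.shape != (len(self.populations), len(self.markers)):
            raise PopdataError(
                f"frequency shape {self.freqs.shape} inconsistent with "
                f"{len(self.populations)} populations x {len(self.markers)} markers"
            )
        vals = self.freqs[~np.isnan(self.freqs)]
        if vals.size and ((vals < 0) | (vals > 1)).any():
            raise PopdataError("frequencies must lie in [0, 1]")

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["marker_id"].tolist()

    def population_index(self, name: str) -> int:
        try:
            return self.populations.index(name)
        except ValueError as exc:
            raise PopdataError(f"unknown population: {name!r}") from exc

    def subset_markers(self, marker_ids: Sequence[str]) -> "FrequencyTable":
        idx = pd.Index(self.markers["marker_id"])
        pos = idx.get_indexer(list(marker_ids))
        if (pos < 0).any():
            missing = [m for m, p in zip(marker_ids, pos) if p < 0]
            raise PopdataError(f"markers not present: {missing[:5]}")
        return FrequencyTable(
            self.freqs[:, pos],
            self.markers.iloc[pos].reset_index(drop=True),
            self.populations,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: marker metadata columns then one column per population."""
        out = self.markers.copy()
        for i, pop in enumerate(self.populations):
            out[pop] = self.freqs[i]
        return out

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FrequencyTable":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        # "In_"-prefixed columns are informativeness annotations, not populations
        pops = [
            c for c in df.columns
            if c not in MARKER_COLUMNS and not c.startswith("In_")
        ]
        if not pops:
            raise PopdataError(f"{path}: no population frequency columns found")
        return cls(df[pops].to_numpy().T, df[MARKER_COLUMNS], pops)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    dialect: str = "auto",
    skip_multiallelic: bool = False,
) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a dosage TSV.

    The dosage TSV dialect is: header row of marker IDs (first column
    ``sample``), one row per sample, entries 0/1/2 and ``NA`` for missing.
    Such files carry no positional metadata, so markers get chrom "1" and
    consecutive positions unless accompanied by a marker table.

    Parameters
    ----------
    dialect : {"auto", "vcf", "dosage"}
    skip_multiallelic : bool
        If True, silently drop multi-allelic VCF records; otherwise raise.
    """
    path = Path(path)
    if not path.exists():
        raise PopdataError(f"no such file: {path}")
    if dialect == "auto":
        dialect = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "dosage"
    if dialect == "vcf":
        return _read_vcf(path, skip_multiallelic)
    if dialect == "dosage":
        return _read_dosage_tsv(path)
    raise PopdataError(f"unknown dialect: {dialect!r}")


def _read_vcf(path: Path, skip_multiallelic: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            if skip_multiallelic:
                continue
            raise PopdataError(
                f"{path}: record {i + 1} ({var.ID or var.POS}) is not biallelic"
            )
        # gts012=True: 0/1/2 = ALT dosage, 3 = missing
        g = np.asarray(var.gt_types, dtype=float)
        g[g == 3] = np.nan
        rows.append(g)
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        meta.append((mid, str(var.CHROM), var.POS, var.REF, var.ALT[0]))
    markers = pd.DataFrame(meta, columns=MARKER_COLUMNS)
    dos = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(dos, markers, samples)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"], index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise PopdataError(f"{path}: parse error: {exc}") from exc
    ids = [str(c) for c in df.columns]
    markers = pd.DataFrame(
        {
            "marker_id": ids,
            "chrom": "1",
            "pos": np.arange(1, len(ids) + 1),
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(
        df.to_numpy(dtype=float), markers, [str(s) for s in df.index]
    )


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF 4.2 file."""
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, grp in G.markers.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        mk = G.markers
        for j in range(G.n_markers):
            calls = [
                "./." if math.isnan(g) else gt_of[g] for g in G.dosages[:, j]
            ]
            fh.write(
                f"{mk.chrom.iat[j]}\t{mk.pos.iat[j]}\t{mk.marker_id.iat[j]}\t"
                f"{mk.ref.iat[j]}\t{mk.alt.iat[j]}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(G.dosages, index=G.samples, columns=G.marker_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _groups(labels: Mapping[str, str], samples: Sequence[str]) -> dict[str, list[int]]:
    lookup = {s: i for i, s in enumerate(samples)}
    out: dict[str, list[int]] = {}
    for sample, pop in labels.items():
        if sample not in lookup:
            raise PopdataError(f"labelled sample {sample!r} not in genotype matrix")
        out.setdefault(pop, []).append(lookup[sample])
    return out


def allele_frequencies(
    G: GenotypeMatrix, labels: Mapping[str, str] | None = None
) -> FrequencyTable:
    """Per-population ALT-allele frequencies.

    freq = (sum of non-missing dosages) / (2 * number of non-missing calls).
    A marker with zero non-missing calls in a population gets NaN.
    """
    labels = labels if labels is not None else G.labels
    if not labels:
        raise PopdataError("no population labels supplied")
    groups = _groups(labels, G.samples)
    empty = [p for p, rows in groups.items() if not rows]
    if empty:
        raise PopdataError(f"populations with no samples: {empty}")
    pops = sorted(groups)
    freqs = np.full((len(pops), G.n_markers), np.nan)
    for i, pop in enumerate(pops):
        sub = G.dosages[groups[pop], :]
        n_called = np.sum(~np.isnan(sub), axis=0)
        with np.errstate(invalid="ignore"):
            freqs[i] = np.nansum(sub, axis=0) / (2.0 * n_called)
        freqs[i, n_called == 0] = np.nan
    return FrequencyTable(freqs, G.markers, pops)


def maf(obj: FrequencyTable | GenotypeMatrix) -> np.ndarray:
    """Per-marker minor-allele frequency, min(p, 1-p) in [0, 0.5].

    For a FrequencyTable the frequency is first pooled (unweighted mean
    across populations); for a GenotypeMatrix it is the overall sample
    frequency.
    """
    if isinstance(obj, FrequencyTable):
        p = np.nanmean(obj.freqs, axis=0)
    else:
        n_called = np.sum(~np.isnan(obj.dosages), axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(obj.dosages, axis=0) / (2.0 * n_called)
        p = np.where(n_called == 0, np.nan, p)
    return np.minimum(p, 1.0 - p)


def missing_rate(G: GenotypeMatrix) -> tuple[float, np.ndarray]:
    """Overall and per-marker fraction of missing genotype calls."""
    miss = np.isnan(G.dosages)
    return float(miss.mean()), miss.mean(axis=0)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Enumerates the full conditional distribution of the heterozygote count
    given the observed allele counts and sums the probabilities of all
    outcomes no more probable than the observed one (no mid-p correction).
    Probabilities are accumulated from log-factorials for stability at the
    extreme tails relevant to array QC (p < 1e-6).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_alt = 2 * n_hom_alt + n_het
    n_rare = min(n_alt, 2 * n - n_alt)
    # feasible het counts share parity with the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    lgamma = math.lgamma
    logp = np.empty(len(hets))
    for k, h in enumerate(hets):
        rare_hom = (n_rare - h) // 2
        com_hom = n - h - rare_hom
        logp[k] = (
            h * math.log(2.0)
            + lgamma(n + 1)
            - lgamma(h + 1)
            - lgamma(rare_hom + 1)
            - lgamma(com_hom + 1)
            + lgamma(n_rare + 1)
            + lgamma(2 * n - n_rare + 1)
            - lgamma(2 * n + 1)
        )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = int(np.where(hets == n_het)[0][0])
    return float(prob[prob <= prob[obs] * (1 + 1e-12)].sum())


def qc_filter(
    G: GenotypeMatrix,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 1e-6,
    by_population: Mapping[str, str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Marker QC: call-rate and per-population exact-HWE filters.

    A marker is removed iff its call rate is below ``call_rate_min`` or its
    exact HWE p-value falls below ``hwe_alpha`` in ANY listed population.
    Populations with fewer than 2 genotyped individuals at a marker are
    skipped for the HWE test.

    Returns
    -------
    retained : list of marker IDs
    report : DataFrame with per-marker call rate, minimum HWE p across
        populations, and which rule (if any) fired.
    """
    if not (0 < call_rate_min <= 1):
        raise PopdataError("call_rate_min must be in (0, 1]")
    if not (0 <= hwe_alpha <= 1):
        raise PopdataError("hwe_alpha must be in [0, 1]")
    labels = by_population if by_population is not None else (G.labels or {})
    groups = _groups(labels, G.samples) if labels else {}

    miss = np.isnan(G.dosages)
    call_rate = 1.0 - miss.mean(axis=0)
    hwe_min = np.ones(G.n_markers)
    for rows in groups.values():
        sub = G.dosages[rows, :]
        for j in range(G.n_markers):
            col = sub[:, j]
            col = col[~np.isnan(col)]
            if col.size < 2:
                continue
            p = hwe_exact_pvalue(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )
            hwe_min[j] = min(hwe_min[j], p)

    low_call = call_rate < call_rate_min
    hwe_fail = hwe_min < hwe_alpha
    rule = np.where(
        low_call & hwe_fail,
        "call_rate+hwe",
        np.where(low_call, "call_rate", np.where(hwe_fail, "hwe", "")),
    )
    report = pd.DataFrame(
        {
            "marker_id": G.marker_ids,
            "call_rate": call_rate,
            "hwe_min_p": hwe_min,
            "removed": low_call | hwe_fail,
            "rule": rule,
        }
    )
    retained = report.loc[~report["removed"], "marker_id"].tolist()
    return retained, report


# ---------------------------------------------------------------------------
# Concordance and LD
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _strand_ambiguous(ref: str, alt: str) -> bool:
    return _COMPLEMENT.get(ref.upper()) == alt.upper()


def genotype_concordance(
    G1: GenotypeMatrix, G2: GenotypeMatrix
) -> tuple[float, pd.Series]:
    """Genotype concordance between two datasets on shared samples/markers.

    Markers are matched by ID. If the REF/ALT alleles are swapped between
    the datasets the second dosage is flipped (g -> 2 - g); swapped
    strand-ambiguous (A/T, C/G) markers are excluded as unresolvable.
    Pairs with a missing call on either side are excluded from the
    denominator.
    """
    shared_samples = [s for s in G1.samples if s in set(G2.samples)]
    m1 = G1.markers.set_index("marker_id")
    m2 = G2.markers.set_index("marker_id")
    shared_markers = [m for m in m1.index if m in m2.index]
    if not shared_samples or not shared_markers:
        raise PopdataError("no shared samples or markers between datasets")

    A = G1.subset_samples(shared_samples).subset_markers(shared_markers)
    B = G2.subset_samples(shared_samples).subset_markers(shared_markers)

    keep: list[int] = []
    flip = np.zeros(len(shared_markers), dtype=bool)
    for j, mid in enumerate(shared_markers):
        r1, a1 = str(m1.loc[mid, "ref"]), str(m1.loc[mid, "alt"])
        r2, a2 = str(m2.loc[mid, "ref"]), str(m2.loc[mid, "alt"])
        if (r1, a1) == (r2, a2):
            keep.append(j)
        elif (r1, a1) == (a2, r2):
            if _strand_ambiguous(r1, a1):
                continue  # unresolvable strand flip
            keep.append(j)
            flip[j] = True
        # alleles incompatible -> excluded
    x = A.dosages[:, keep]
    y = B.dosages[:, keep]
    y = np.where(flip[keep][None, :], 2.0 - y, y)

    both = ~np.isnan(x) & ~np.isnan(y)
    if both.sum() == 0:
        raise PopdataError("no comparable genotype pairs")
    agree = (x == y) & both
    per_sample = pd.Series(
        np.divide(
            agree.sum(axis=1),
            both.sum(axis=1),
            out=np.full(len(shared_samples), np.nan),
            where=both.sum(axis=1) > 0,
        ),
        index=shared_samples,
        name="concordance",
    )
    return float(agree.sum() / both.sum()), per_sample


def ld_r2(G: GenotypeMatrix, window_bp: int) -> pd.DataFrame:
    """Squared dosage correlation for same-chromosome marker pairs.

    Pairs are restricted to markers at most ``window_bp`` apart (closed
    interval). Monomorphic markers yield NaN, reported as such.
    """
    mk = G.markers
    out: list[tuple] = []
    for _, grp in mk.groupby("chrom", sort=False):
        order = grp.sort_values("pos")
        idx = order.index.to_numpy()
        pos = order["pos"].to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if pos[b] - pos[a] > window_bp:
                    break
                x = G.dosages[:, idx[a]]
                y = G.dosages[:, idx[b]]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
                    r2 = np.nan
                else:
                    r2 = float(np.corrcoef(x[ok], y[ok])[0, 1] ** 2)
                out.append(
                    (
                        mk.marker_id.iat[idx[a]],
                        mk.marker_id.iat[idx[b]],
                        mk.chrom.iat[idx[a]],
                        int(pos[b] - pos[a]),
                        r2,
                    )
                )
    return pd.DataFrame(
        out, columns=["marker_a", "marker_b", "chrom", "distance_bp", "r2"]
    )
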