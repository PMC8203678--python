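"""Synthetic barseq data with known ground truth.

Generators for every input the analysis consumes: strain catalogs with paired
20-bp uptag/downtag barcodes, screen designs (treatment triplicates plus
diluent/date-matched controls), tag-level count matrices under a
negative-binomial noise model over lognormal baseline abundances, single-end
50-bp reads, and toy gene-set ontologies with nested term lineages.  Every
generator is a pure function of its arguments including the seed, so each
downstream stage can be tested against planted truth without any downloads.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "StrainCatalog",
    "ScreenDesign",
    "TruthTable",
    "NBParams",
    "make_catalog",
    "make_design",
    "make_truth",
    "make_group_truth",
    "simulate_counts",
    "simulate_reads",
    "make_toy_ontology",
    "UPTAG_FLANK5",
    "UPTAG_FLANK3",
    "DOWNTAG_FLANK5",
    "DOWNTAG_FLANK3",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


# Internal primer segments adjacent to the barcodes; the 3' flank appears in
# the read as the reverse complement of the primer on the opposite strand.
UPTAG_FLANK5 = "GATGTCCACGAGGTCTCT"
UPTAG_FLANK3 = _revcomp("GTCGACCTGCAGCGTACG")  # CGTACGCTGCAGGTCGAC
DOWNTAG_FLANK5 = "CGGTGTCGGTCTCGTAG"
DOWNTAG_FLANK3 = _revcomp("GAAAACGAGCTCGAATTCATCG")  # CGATGAATTCGAGCTCGTTTTC

READ_LENGTH = 50
TAG_LENGTH = 20


# ---------------------------------------------------------------------------
# Strain catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrainCatalog:
    """Deletion-strain identities with their uptag and downtag barcodes.

    ``frame`` has columns ``strain_id, gene, uptag, downtag``.  All tags are
    pairwise distinct, exactly ``tag_len`` nt over {A,C,G,T}, and separated by
    at least ``min_hamming`` mismatches.
    """

    frame: pd.DataFrame
    min_hamming: int = 5

    def __post_init__(self) -> None:
        self.validate()

    @property
    def strains(self) -> pd.Index:
        return pd.Index(self.frame["strain_id"])

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.frame["gene"])

    @property
    def tags(self) -> list[str]:
        return list(self.frame["uptag"]) + list(self.frame["downtag"])

    def tag_to_strain(self) -> dict[str, tuple[str, str]]:
        """Map every tag to ``(strain_id, kind)`` with kind in {'up', 'down'}."""
        out: dict[str, tuple[str, str]] = {}
        for row in self.frame.itertuples(index=False):
            out[row.uptag] = (row.strain_id, "up")
            out[row.downtag] = (row.strain_id, "down")
        return out

    def validate(self) -> None:
        tags = self.tags
        if len(set(tags)) != len(tags):
            raise ValueError("catalog tags are not pairwise distinct")
        lengths = {len(t) for t in tags}
        if lengths and lengths != {len(tags[0])}:
            raise ValueError("catalog tags have inconsistent lengths")
        for t in tags[:2]:
            if set(t) - set("ACGT"):
                raise ValueError(f"tag {t!r} is not over {{A,C,G,T}}")

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, min_hamming: int = 5) -> "StrainCatalog":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return cls(frame=frame, min_hamming=min_hamming)


def _encode(seqs: Sequence[str]) -> np.ndarray:
    """Sequences -> (n, L) uint8 matrix of base codes 0..3."""
    lut = np.full(256, 255, dtype=np.uint8)
    for code, base in enumerate("ACGT"):
        lut[ord(base)] = code
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    mat = lut[arr].reshape(len(seqs), -1)
    if (mat == 255).any():
        raise ValueError("non-ACGT character in sequence")
    return mat


def _decode(mat: np.ndarray) -> list[str]:
    return [bytes(_BASES[row]).decode() for row in mat]


def _min_distance_offenders(mat: np.ndarray, floor: int, chunk: int = 512) -> set[int]:
    """Indices of tags that sit closer than ``floor`` to an earlier tag."""
    n, L = mat.shape
    onehot = np.zeros((n, 4 * L), dtype=np.float32)
    onehot[np.arange(n)[:, None], np.arange(L) * 4 + mat] = 1.0
    bad: set[int] = set()
    for start in range(0, n, chunk):
        rows = onehot[start : start + chunk]
        matches = rows @ onehot.T  # number of agreeing positions
        dist = L - matches
        for i_local, j in zip(*np.nonzero(dist < floor)):
            i = start + int(i_local)
            j = int(j)
            if i == j:
                continue
            bad.add(max(i, j))  # resample the later of the pair
    return bad


def make_catalog(
    n_strains: int,
    tag_len: int = TAG_LENGTH,
    min_hamming: int = 5,
    seed: int = 0,
) -> StrainCatalog:
    """Generate a catalog of ``n_strains`` strains with 2*n distinct barcodes.

    Tags are sampled uniformly and resampled until the minimum pairwise
    Hamming distance reaches ``min_hamming``.  Raises ``ValueError`` when the
    sequence space cannot hold the request and ``RuntimeError`` if the
    distance floor cannot be reached in a bounded number of rounds.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if not (tag_len >= min_hamming >= 0):
        raise ValueError("need tag_len >= min_hamming >= 0")
    n_tags = 2 * n_strains
    if math.log(n_tags) > tag_len * math.log(4) - 1:
        raise ValueError(
            f"tag space 4^{tag_len} too small for {n_tags} tags at Hamming >= {min_hamming}"
        )
    rng = np.random.default_rng(seed)
    mat = rng.integers(0, 4, size=(n_tags, tag_len), dtype=np.uint8)
    for _round in range(60):
        bad = _min_distance_offenders(mat, min_hamming)
        if not bad:
            break
        idx = sorted(bad)
        mat[idx] = rng.integers(0, 4, size=(len(idx), tag_len), dtype=np.uint8)
    else:
        raise RuntimeError(
            f"could not reach min pairwise Hamming {min_hamming} for {n_tags} tags"
        )
    tags = _decode(mat)
    strain_ids = [f"Y{chr(65 + i % 16)}L{i:04d}W-del" for i in range(n_strains)]
    genes = [f"GENE{i:04d}" for i in range(n_strains)]
    frame = pd.DataFrame(
        {
            "strain_id": strain_ids,
            "gene": genes,
            "uptag": tags[:n_strains],
            "downtag": tags[n_strains:],
        }
    )
    return StrainCatalog(frame=frame, min_hamming=min_hamming)


# ---------------------------------------------------------------------------
# Screen design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenDesign:
    """Sample sheet: sample -> screen/condition/replicate/compound/dose/diluent/date.

    Screen ids follow the ``<compound>_<dose>_<date>`` convention; control
    samples are shared by every screen with the same diluent and date.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def samples(self) -> pd.Index:
        return pd.Index(self.frame["sample_id"])

    @property
    def screen_ids(self) -> list[str]:
        mask = self.frame["condition"] == "treatment"
        return list(dict.fromkeys(self.frame.loc[mask, "screen_id"]))

    def treatment_samples(self, screen_id: str) -> list[str]:
        f = self.frame
        mask = (f["screen_id"] == screen_id) & (f["condition"] == "treatment")
        return list(f.loc[mask, "sample_id"])

    def control_samples(self, screen_id: str) -> list[str]:
        """Controls matched to a screen by diluent and date."""
        f = self.frame
        row = f[(f["screen_id"] == screen_id) & (f["condition"] == "treatment")]
        if row.empty:
            raise KeyError(f"unknown screen_id {screen_id!r}")
        diluent, date = row.iloc[0]["diluent"], row.iloc[0]["date"]
        mask = (
            (f["condition"] == "control")
            & (f["diluent"] == diluent)
            & (f["date"] == date)
        )
        return list(f.loc[mask, "sample_id"])

    def replicate_groups(self) -> dict[str, list[str]]:
        """Samples grouped by replicate structure (screen for treatments,
        diluent+date batch for controls)."""
        groups: dict[str, list[str]] = {}
        for row in self.frame.itertuples(index=False):
            key = (
                row.screen_id
                if row.condition == "treatment"
                else f"control_{row.diluent}_{row.date}"
            )
            groups.setdefault(key, []).append(row.sample_id)
        return groups

    def validate(self) -> None:
        f = self.frame
        required = {
            "sample_id", "screen_id", "condition", "replicate",
            "compound", "dose", "diluent", "date",
        }
        missing = required - set(f.columns)
        if missing:
            raise ValueError(f"design missing columns {sorted(missing)}")
        if f["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design")
        bad = set(f["condition"]) - {"control", "treatment"}
        if bad:
            raise ValueError(f"invalid condition values {sorted(bad)}")
        dup = f.duplicated(subset=["screen_id", "condition", "replicate"])
        if dup.any():
            raise ValueError("replicate indices not unique within (screen, condition)")
        for screen_id in self.screen_ids:
            if not self.control_samples(screen_id):
                raise ValueError(f"screen {screen_id!r} has no matched control")

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScreenDesign":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        frame["replicate"] = frame["replicate"].astype(int)
        return cls(frame=frame)


def make_design(
    compounds: Sequence[tuple[str, str, str]],
    n_replicates: int = 3,
    date: str = "190801",
) -> ScreenDesign:
    """Build a design with one screen per ``(name, dose, diluent)`` entry.

    Treatment samples come in ``n_replicates`` biological replicates; one set
    of control replicates is created per (diluent, date) batch and shared by
    every screen in that batch.  ``date`` may be a single yymmdd string or a
    per-compound sequence.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not compounds:
        raise ValueError("compounds must be non-empty")
    dates = [date] * len(compounds) if isinstance(date, str) else list(date)
    if len(dates) != len(compounds):
        raise ValueError("one date per compound required")
    seen: set[tuple[str, str, str]] = set()
    rows = []
    for (name, dose, diluent), d in zip(compounds, dates):
        if not dose:
            raise ValueError("dose must be a non-empty string")
        key = (name, dose, d)
        if key in seen:
            raise ValueError(f"duplicate screen (compound, dose, date) = {key}")
        seen.add(key)
        screen_id = f"{name}_{dose}_{d}"
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{screen_id}_T{rep}",
                    "screen_id": screen_id,
                    "condition": "treatment",
                    "replicate": rep,
                    "compound": name,
                    "dose": dose,
                    "diluent": diluent,
                    "date": d,
                }
            )
    for diluent, d in dict.fromkeys(
        (c[2], dd) for c, dd in zip(compounds, dates)
    ):
        batch = f"control_{diluent}_{d}"
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{batch}_C{rep}",
                    "screen_id": batch,
                    "condition": "control",
                    "replicate": rep,
                    "compound": diluent,
                    "dose": "0",
                    "diluent": diluent,
                    "date": d,
                }
            )
    return ScreenDesign(frame=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Planted log2 fold changes per (gene, screen); absent genes are 0.

    ``lfc`` is genes x screen_ids (0 = no effect, negative = depleted).
    ``planted_term`` optionally records the gene-set term planted per screen;
    ``screen_groups`` labels screens that share a sensitivity signature.
    """

    lfc: pd.DataFrame
    planted_term: dict[str, str] = field(default_factory=dict)
    screen_groups: dict[str, str] = field(default_factory=dict)

    def true_lfc(self, gene: str, screen_id: str) -> float:
        if gene in self.lfc.index and screen_id in self.lfc.columns:
            return float(self.lfc.loc[gene, screen_id])
        return 0.0

    def planted_genes(self, screen_id: str) -> list[str]:
        col = self.lfc[screen_id]
        return list(col.index[col != 0.0])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.lfc.rename_axis("gene").to_csv(path, sep="\t")
        return path


def make_truth(
    catalog: StrainCatalog,
    design: ScreenDesign,
    planted: Mapping[str, Mapping[str, float]] | None = None,
    planted_term: Mapping[str, str] | None = None,
    screen_groups: Mapping[str, str] | None = None,
) -> TruthTable:
    """Assemble a TruthTable; ``planted`` maps screen_id -> {gene: true_lfc}."""
    genes = list(catalog.genes)
    lfc = pd.DataFrame(0.0, index=genes, columns=design.screen_ids)
    for screen_id, effects in (planted or {}).items():
        if screen_id not in lfc.columns:
            raise KeyError(f"unknown screen_id {screen_id!r}")
        for gene, value in effects.items():
            if gene not in lfc.index:
                raise KeyError(f"planted gene {gene!r} not in catalog")
            lfc.loc[gene, screen_id] = float(value)
    return TruthTable(
        lfc=lfc,
        planted_term=dict(planted_term or {}),
        screen_groups=dict(screen_groups or {}),
    )


def make_group_truth(
    catalog: StrainCatalog,
    design: ScreenDesign,
    groups: Mapping[str, Sequence[str]],
    n_shared: int = 60,
    n_private: int = 20,
    lfc: float = -2.0,
    seed: int = 0,
) -> TruthTable:
    """Truth with groups of screens sharing a sensitivity signature.

    Each group gets ``n_shared`` marker genes depleted in all of its screens;
    every screen additionally receives ``n_private`` unique markers.  Screens
    not listed in ``groups`` are treated as singleton groups of one.
    """
    rng = np.random.default_rng(seed)
    genes = list(catalog.genes)
    all_screens = design.screen_ids
    grouped = {s for members in groups.values() for s in members}
    full_groups: dict[str, list[str]] = {k: list(v) for k, v in groups.items()}
    for s in all_screens:
        if s not in grouped:
            full_groups[f"singleton_{s}"] = [s]
    need = len(full_groups) * n_shared + len(all_screens) * n_private
    if need > len(genes):
        raise ValueError(f"need {need} marker genes but catalog has {len(genes)}")
    pool = list(rng.permutation(genes))
    planted: dict[str, dict[str, float]] = {s: {} for s in all_screens}
    screen_groups: dict[str, str] = {}
    for label, members in full_groups.items():
        shared = [pool.pop() for _ in range(n_shared)]
        for s in members:
            screen_groups[s] = label
            for g in shared:
                planted[s][g] = lfc
            for _ in range(n_private):
                planted[s][pool.pop()] = lfc
    return make_truth(catalog, design, planted, screen_groups=screen_groups)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

@dataclass
class NBParams:
    """Noise model for simulated tag counts.

    Baseline strain abundances are lognormal(``baseline_log_mean``,
    ``baseline_log_sd``); counts per tag are negative binomial with
    ``dispersion`` alpha (var = mu + alpha*mu^2) around
    baseline * 2^true_lfc * library_size.
    """

    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 0.7
    dispersion: float = 0.05
    library_sizes: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.library_sizes is not None:
            if any(v <= 0 for v in self.library_sizes.values()):
                raise ValueError("library_sizes must be positive")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-8:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_counts(
    catalog: StrainCatalog,
    design: ScreenDesign,
    truth: TruthTable,
    params: NBParams,
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate a tag-level count matrix (tags x samples).

    Uptag and downtag of a strain are independent NB draws around the shared
    strain expectation.  Control samples see the baseline; treatment samples
    of screen s see baseline * 2^true_lfc(gene, s); both are scaled by the
    sample's library size.  Deterministic given ``params.seed``.
    """
    missing = set(truth.lfc.index) - set(catalog.genes)
    if missing:
        raise ValueError(f"truth genes absent from catalog: {sorted(missing)[:5]}")
    rng = np.random.default_rng(params.seed)
    genes = list(catalog.genes)
    n = len(genes)
    baseline = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, size=n)
    lib = params.library_sizes or {}
    columns: dict[str, np.ndarray] = {}
    for row in design.frame.itertuples(index=False):
        if row.condition == "treatment":
            lfc = truth.lfc.reindex(genes)[row.screen_id].to_numpy(dtype=float)
        else:
            lfc = np.zeros(n)
        mu = baseline * np.exp2(lfc) * float(lib.get(row.sample_id, 1.0))
        up = _nb_draw(rng, mu, params.dispersion)
        down = _nb_draw(rng, mu, params.dispersion)
        columns[row.sample_id] = np.concatenate([up, down])
    tags = list(catalog.frame["uptag"]) + list(catalog.frame["downtag"])
    counts = pd.DataFrame(columns, index=pd.Index(tags, name="tag"))
    return counts, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _read_template(tag: str, kind: str) -> str:
    if kind == "up":
        read = UPTAG_FLANK5 + tag + UPTAG_FLANK3
    else:
        read = DOWNTAG_FLANK5 + tag + DOWNTAG_FLANK3
    read = read[:READ_LENGTH]
    return read + "A" * (READ_LENGTH - len(read))


def simulate_reads(
    counts: pd.DataFrame,
    catalog: StrainCatalog,
    error_rate: float = 0.0,
    seed: int = 0,
    out_dir: str | Path = ".",
    gz: bool = False,
) -> dict[str, Path]:
    """Emit one FASTQ per sample column of ``counts``.

    Each read is 50 nt: 5' flank + 20-nt tag + 3' flank (truncated to 50),
    with i.i.d. per-base substitution errors at ``error_rate``.  At
    ``error_rate=0`` the read multiset per tag matches the counts exactly.
    """
    if not (0 <= error_rate < 0.25):
        raise ValueError("error_rate must be in [0, 0.25)")
    tag_map = catalog.tag_to_strain()
    unknown = [t for t in counts.index if t not in tag_map]
    if unknown:
        raise ValueError(f"tags absent from catalog: {unknown[:5]}")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    templates = _encode(
        [_read_template(t, tag_map[t][1]) for t in counts.index]
    )
    paths: dict[str, Path] = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=np.int64)
        reads = np.repeat(templates, col, axis=0)
        if error_rate > 0 and reads.size:
            mask = rng.random(reads.shape) < error_rate
            # substitute with a different base: add 1..3 mod 4
            shift = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
            reads = np.where(mask, (reads + shift) % 4, reads)
        suffix = ".fastq.gz" if gz else ".fastq"
        path = out_dir / f"{sample}{suffix}"
        opener = gzip.open if gz else open
        qual = "I" * READ_LENGTH
        with opener(path, "wt") as fh:
            for i, row in enumerate(_decode(reads)):
                fh.write(f"@{sample}_{i}\n{row}\n+\n{qual}\n")
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# Toy ontology
# ---------------------------------------------------------------------------

def make_toy_ontology(
    n_terms: int = 200,
    n_genes: int = 1000,
    depth: int = 4,
    seed: int = 0,
):
    """Generate a toy gene-set collection plus its DAG of term lineages.

    The root term annotates every gene; each deeper term's gene set is a
    subset of its parent's, so the true-path (subset) rule holds along every
    lineage.  Term sizes deliberately span values below 5, within [5, 300]
    and above 300 so the size filter is exercised.  Returns
    ``(GeneSetCollection, networkx.DiGraph)`` with edges child -> parent.
    """
    from .enrichment import GeneSetCollection  # local import avoids a cycle

    if not (n_terms >= depth >= 1):
        raise ValueError("need n_terms >= depth >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    root = "TOY:0000000"
    sets: dict[str, frozenset] = {root: frozenset(genes)}
    names = {root: "toy root"}
    parents: dict[str, str] = {}
    levels: dict[int, list[str]] = {0: [root]}
    # sizes that exercise the [5, 300] filter on both sides
    forced = {}
    if n_genes >= 302 and n_terms >= 4:
        forced = {"TOY:9000001": 4, "TOY:9000002": 301}
    # geometric size decay per level, jittered per term
    for i in range(1, n_terms - len(forced)):
        term = f"TOY:{i:07d}"
        level = 1 + int(rng.integers(0, depth)) if depth > 1 else 1
        level = min(level, max(levels) + 1)
        parent_pool = levels.get(level - 1) or levels[max(levels)]
        parent = parent_pool[int(rng.integers(0, len(parent_pool)))]
        frac = float(rng.uniform(0.25, 0.6))
        parent_genes = sorted(sets[parent])
        size = max(2, int(round(frac * len(parent_genes) * rng.uniform(0.5, 1.0))))
        size = min(size, len(parent_genes))
        members = rng.choice(parent_genes, size=size, replace=False)
        sets[term] = frozenset(members.tolist())
        names[term] = f"toy term {i}"
        parents[term] = parent
        levels.setdefault(level, []).append(term)
    for term, size in forced.items():
        members = rng.choice(genes, size=size, replace=False)
        sets[term] = frozenset(members.tolist())
        names[term] = f"toy forced size {size}"
        parents[term] = root
    dag = nx.DiGraph()
    dag.add_nodes_from(sets)
    for child, parent in parents.items():
        dag.add_edge(child, parent, relation="is_a")
    collection = GeneSetCollection(
        sets=sets, names=names, universe=frozenset(genes)
    )
    return collection, dag
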