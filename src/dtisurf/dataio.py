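"""Readers, writers and containers for the three raw inputs.

A drug-target interaction study starts from three files: per-protein
position-specific scoring matrices (PSSMs) in the ASCII dialect that
``psiblast -out_ascii_pssm`` emits, a table of 881-bit molecular
substructure fingerprints (one row per drug), and a two-column list of
experimentally validated drug-target pairs that defines a bipartite
interaction network.  This module parses all three, samples balanced
negative pairs from the non-edges of the network, and assembles the
labelled pair samples the classifier consumes.

Only the first 20 columns of the PSSM body (the log-odds block) are
retained; the weighted-percentage block and the trailing statistics are
ignored.  PSSMs are usually generated externally with an e-value cutoff
of 0.001 and three search iterations; this package never invokes
PSI-BLAST itself.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Number of bits in a molecular substructure fingerprint.
FINGERPRINT_BITS = 881

#: Canonical amino-acid column order of a PSI-BLAST PSSM.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

POSITIVE = "positive"
NEGATIVE = "negative"


class FormatError(ValueError):
    """Raised when an input file does not follow its expected dialect."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PSSM:
    """An L x 20 position-specific scoring matrix for one protein.

    Rows are sequence positions, columns the 20 amino-acid types in the
    order :data:`AMINO_ACIDS`.  Entries are log-odds substitution scores
    and may be negative, zero or positive.
    """

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM for {self.protein_id!r} must be L x 20, "
                f"got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"PSSM for {self.protein_id!r} has no rows")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class DrugFingerprint:
    """An 881-bit binary substructure fingerprint for one drug."""

    drug_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.shape != (FINGERPRINT_BITS,):
            raise ValueError(
                f"fingerprint for {self.drug_id!r} must have length "
                f"{FINGERPRINT_BITS}, got {bits.shape}"
            )
        if not np.isin(bits, (0, 1)).all():
            raise ValueError(f"fingerprint for {self.drug_id!r} has non-binary entries")
        self.bits = bits.astype(np.uint8)


@dataclass(frozen=True)
class InteractionNetwork:
    """Bipartite drug-target network with validated interactions as edges."""

    drugs: tuple
    targets: tuple
    positive_edges: frozenset

    def __post_init__(self) -> None:
        drug_set, target_set = set(self.drugs), set(self.targets)
        for d, t in self.positive_edges:
            if d not in drug_set or t not in target_set:
                raise ValueError(f"edge ({d!r}, {t!r}) references an unknown node")

    @property
    def n_possible_pairs(self) -> int:
        """Size of the full bipartite pair space |drugs| x |targets|."""
        return len(self.drugs) * len(self.targets)

    @property
    def n_positive(self) -> int:
        return len(self.positive_edges)


@dataclass
class PairSample:
    """One labelled drug-protein pair: the classifier's unit of data.

    ``features`` is the protein feature block followed by the 881
    fingerprint bits.
    """

    drug_id: str
    protein_id: str
    label: str
    features: np.ndarray


# ---------------------------------------------------------------------------
# IO helpers
# ---------------------------------------------------------------------------


def _looks_like_path(source) -> bool:
    if isinstance(source, Path):
        return True
    if not isinstance(source, str) or "\n" in source or len(source) > 1024:
        return False
    try:
        return Path(source).is_file()
    except OSError:
        return False


def _read_text(source) -> str:
    """Return text content from a path (gzip transparent) or pass a str through."""
    if _looks_like_path(source):
        path = Path(source)
        if path.suffix == ".gz":
            with gzip.open(path, "rt") as fh:
                return fh.read()
        return path.read_text()
    return source


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------


def parse_pssm(source, protein_id: str = "") -> PSSM:
    """Parse PSI-BLAST ASCII PSSM content into an L x 20 score matrix.

    Accepts a path or raw text.  Body rows look like::

        1 M   -2 -1 ... (20 log-odds ints) (20 percentage ints) 0.35 0.12

    Only the first 20 score columns are kept.  A body row with fewer than
    20 parsable integers raises :class:`FormatError` naming the line.
    """
    text = _read_text(source)
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if len(tokens) < 2 or not tokens[0].isdigit():
            continue
        if not (len(tokens[1]) == 1 and tokens[1].isalpha()):
            continue
        score_tokens = tokens[2:22]
        try:
            scores = [int(tok) for tok in score_tokens]
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer score in PSSM body") from exc
        if len(scores) != 20:
            raise FormatError(
                f"line {lineno}: expected 20 log-odds scores, got {len(scores)}"
            )
        rows.append(scores)
    if not rows:
        raise FormatError("no PSSM body rows found")
    return PSSM(protein_id=protein_id, scores=np.array(rows, dtype=float))


def write_pssm(pssm: PSSM) -> str:
    """Render a PSSM back into the PSI-BLAST ASCII dialect.

    The percentage block is filled with zeros and the per-row trailing
    statistics with placeholders; :func:`parse_pssm` ignores both.
    """
    header = "  ".join(AMINO_ACIDS) + "   " + "  ".join(AMINO_ACIDS)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + header,
    ]
    for i, row in enumerate(pssm.scores, start=1):
        residue = AMINO_ACIDS[(i - 1) % 20]
        scores = " ".join(f"{int(round(v)):3d}" for v in row)
        pct = " ".join("  0" for _ in range(20))
        lines.append(f"{i:5d} {residue}  {scores}  {pct}  0.00 0.00")
    lines += ["", "                      K         Lambda", ""]
    return "\n".join(lines) + "\n"


def read_pssm_dir(directory, suffixes: Sequence[str] = (".pssm", ".txt")) -> dict:
    """Read every PSSM file in *directory*; protein id = file stem."""
    directory = Path(directory)
    pssms = {}
    for path in sorted(directory.iterdir()):
        if path.suffix in suffixes or (
            path.suffix == ".gz" and Path(path.stem).suffix in suffixes
        ):
            pid = Path(path.stem).stem if path.suffix == ".gz" else path.stem
            pssms[pid] = parse_pssm(path, protein_id=pid)
    if not pssms:
        raise FormatError(f"no PSSM files found in {directory}")
    return pssms


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------


def _split_row(line: str, delim: str) -> list:
    return [f.strip() for f in line.split(delim)]


def read_fingerprints(source) -> dict:
    """Read a fingerprint table into ``{drug_id: DrugFingerprint}``.

    Two layouts are accepted (CSV or TSV, gzip transparent): ``drug_id``
    plus 881 separate 0/1 fields, or ``drug_id`` plus a single
    881-character 0/1 string.
    """
    text = _read_text(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty fingerprint table")
    delim = "\t" if "\t" in lines[0] else ","
    out = {}
    for line in lines:
        fields = _split_row(line, delim)
        drug_id = fields[0]
        if len(fields) == 2:
            bitstr = fields[1]
            if len(bitstr) != FINGERPRINT_BITS or set(bitstr) - {"0", "1"}:
                raise FormatError(
                    f"drug {drug_id!r}: bit string must be {FINGERPRINT_BITS} "
                    "characters of 0/1"
                )
            bits = np.frombuffer(bitstr.encode(), dtype=np.uint8) - ord("0")
        elif len(fields) == FINGERPRINT_BITS + 1:
            try:
                bits = np.array([int(f) for f in fields[1:]], dtype=np.uint8)
            except ValueError as exc:
                raise FormatError(f"drug {drug_id!r}: non-binary field") from exc
        else:
            raise FormatError(
                f"drug {drug_id!r}: expected {FINGERPRINT_BITS} bit fields or one "
                f"bit string, got {len(fields) - 1} fields"
            )
        try:
            out[drug_id] = DrugFingerprint(drug_id, bits)
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
    return out


def write_fingerprints(fps: Mapping[str, DrugFingerprint]) -> str:
    """Render fingerprints as CSV ``drug_id,<881-char bit string>``."""
    lines = []
    for drug_id in fps:
        fp = fps[drug_id]
        lines.append(f"{drug_id}," + "".join(map(str, fp.bits.tolist())))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------


def read_interactions(
    source,
    drugs: Iterable[str] = (),
    targets: Iterable[str] = (),
) -> InteractionNetwork:
    """Read a ``drug_id<TAB>protein_id`` table into a bipartite network.

    Duplicate rows are collapsed (count logged).  The node sets are the
    union of ids seen in the table and any externally supplied universe,
    in first-seen order.
    """
    text = _read_text(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty interaction table")
    delim = "\t" if "\t" in lines[0] else ","
    drug_order = list(dict.fromkeys(drugs))
    target_order = list(dict.fromkeys(targets))
    seen_d, seen_t = set(drug_order), set(target_order)
    edges = []
    for lineno, line in enumerate(lines, start=1):
        fields = _split_row(line, delim)
        if len(fields) != 2:
            raise FormatError(f"line {lineno}: expected two columns, got {len(fields)}")
        d, t = fields
        if d not in seen_d:
            seen_d.add(d)
            drug_order.append(d)
        if t not in seen_t:
            seen_t.add(t)
            target_order.append(t)
        edges.append((d, t))
    unique_edges = frozenset(edges)
    n_dup = len(edges) - len(unique_edges)
    if n_dup:
        logger.info("collapsed %d duplicate interaction rows", n_dup)
    return InteractionNetwork(tuple(drug_order), tuple(target_order), unique_edges)


def write_interactions(net: InteractionNetwork) -> str:
    lines = [f"{d}\t{t}" for d, t in sorted(net.positive_edges)]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# negative sampling and dataset assembly
# ---------------------------------------------------------------------------


def sample_negatives(net: InteractionNetwork, n: int | None = None, seed: int = 0):
    """Sample *n* non-interacting pairs uniformly without replacement.

    Interaction networks are sparse, so the unlabelled non-edges vastly
    outnumber validated edges; drawing as many random non-edges as there
    are edges (the default) yields the balanced training set the
    classifier expects.  Reproducible under *seed*.
    """
    if n is None:
        n = net.n_positive
    pos_idx = {
        net.drugs.index(d) * len(net.targets) + net.targets.index(t)
        for d, t in net.positive_edges
    }
    pool = np.array(
        [i for i in range(net.n_possible_pairs) if i not in pos_idx], dtype=np.int64
    )
    if n > pool.size:
        raise ValueError(
            f"requested {n} negatives but only {pool.size} non-edges exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n, replace=False)
    n_t = len(net.targets)
    return [(net.drugs[i // n_t], net.targets[i % n_t]) for i in sorted(chosen.tolist())]


def assemble_dataset(
    net: InteractionNetwork,
    negatives: Sequence,
    protein_features: Mapping[str, np.ndarray],
    fingerprints: Mapping[str, DrugFingerprint],
) -> list:
    """Build labelled pair samples: protein feature block ++ fingerprint bits.

    One sample per positive edge and per supplied negative pair.  A
    missing feature or fingerprint entry raises ``KeyError`` naming the
    offending id.
    """

    def _features(d: str, t: str) -> np.ndarray:
        if t not in protein_features:
            raise KeyError(f"no protein features for {t!r}")
        if d not in fingerprints:
            raise KeyError(f"no fingerprint for {d!r}")
        fp = fingerprints[d]
        bits = fp.bits if isinstance(fp, DrugFingerprint) else np.asarray(fp)
        return np.concatenate([np.asarray(protein_features[t], dtype=float), bits])

    if not negatives:
        logger.warning("assembling a dataset with no negative pairs")
    samples = [
        PairSample(d, t, POSITIVE, _features(d, t)) for d, t in sorted(net.positive_edges)
    ]
    samples += [PairSample(d, t, NEGATIVE, _features(d, t)) for d, t in negatives]
    return samples


def dataset_arrays(samples: Sequence[PairSample]):
    """Stack pair samples into ``(X, y)`` with y=1 for interacting pairs."""
    X = np.vstack([s.features for s in samples])
    y = np.array([1 if s.label == POSITIVE else 0 for s in samples], dtype=int)
    return X, y
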