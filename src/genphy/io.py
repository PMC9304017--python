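"""File formats: NEXUS character matrices, chain logs, YAML run configs.

Character matrices are NEXUS standard-datatype alignments.  The
canonical on-disk form codes one row per species with symbols 0/1/2 --
the number of copies of the red allele in a diploid genotype -- which is
lossless for per-species counts ``(n=2, r)``; ``?``/``-`` mark missing
data.  Haploid 0/1 matrices (one row per gene copy, grouped onto species
with a label mapping) are also read.  Nucleotide alignments can be
recoded to biallelic characters, dropping sites with more than two
observed states.

Chain output is a tab-separated state log (one row per sampled
generation) plus a NEXUS trees block whose newick strings carry the
``[&hc=<int>]`` height-class annotations, so shared divergences survive
the round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from genphy.likelihood import BiallelicMatrix
from genphy.mcmc import Trace
from genphy.priors import ExponentialDist, GammaDist, PriorConfig
from genphy.tree import GeneralizedTree, parse_tree

__all__ = [
    "read_character_nexus",
    "write_character_nexus",
    "nucleotide_to_biallelic",
    "RunConfig",
    "load_run_config",
    "write_state_log",
    "read_state_log",
    "write_tree_log",
    "read_tree_log",
]


# ---------------------------------------------------------------------------
# NEXUS character matrices
# ---------------------------------------------------------------------------


def _parse_nexus_matrix(text: str) -> dict[str, str]:
    """Minimal reader for the standard-data matrix block we write."""
    lines = text.splitlines()
    rows: dict[str, str] = {}
    in_matrix = False
    for raw in lines:
        line = raw.strip()
        low = line.lower()
        if low.startswith("matrix"):
            in_matrix = True
            continue
        if not in_matrix:
            continue
        if line.startswith(";") or low.startswith("end"):
            break
        if not line:
            continue
        parts = line.rstrip(";").split()
        if len(parts) < 2:
            continue
        label = parts[0].strip("'\"")
        rows[label] = rows.get(label, "") + "".join(parts[1:])
    if not rows:
        raise ValueError("no matrix block found in NEXUS input")
    return rows


def read_character_nexus(
    path: str | Path,
    species_map: Mapping[str, str] | None = None,
    variable_only: bool = False,
) -> BiallelicMatrix:
    """Read a biallelic character matrix from NEXUS standard data.

    Symbols 0/1/2 count red-allele copies of a diploid genotype (two
    copies per cell); a matrix containing no ``2`` and whose labels map
    many-to-one onto species via ``species_map`` is read as haploid rows
    (one copy per cell) grouped by species.  ``?`` and ``-`` are
    missing.
    """
    text = Path(path).read_text()
    rows = _parse_nexus_matrix(text)
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValueError("rows have unequal lengths")
    m = lengths.pop()
    diploid = any("2" in s for s in rows.values()) or species_map is None

    species_of = dict(species_map) if species_map else {lab: lab for lab in rows}
    unknown = set(rows) - set(species_of)
    if unknown:
        raise ValueError(f"labels missing from the species map: {sorted(unknown)}")
    species = tuple(sorted(set(species_of.values())))
    col = {s: i for i, s in enumerate(species)}
    n = np.zeros((m, len(species)), dtype=np.int64)
    r = np.zeros((m, len(species)), dtype=np.int64)
    per_cell = 2 if diploid else 1
    for label, seq in rows.items():
        j = col[species_of[label]]
        for i, ch in enumerate(seq):
            if ch in "?-":
                continue
            if ch not in "012" or (not diploid and ch == "2"):
                raise ValueError(f"bad state {ch!r} in row {label!r}")
            n[i, j] += per_cell
            r[i, j] += int(ch)
    if np.any(r > n):
        raise ValueError("red counts exceed sampled copies; check the coding")
    return BiallelicMatrix(species, n, r, variable_only=variable_only)


def write_character_nexus(matrix: BiallelicMatrix, path: str | Path) -> None:
    """Write a matrix as NEXUS standard data (0/1/2 diploid coding; a
    matrix whose counts are all 0/1 is written as haploid 0/1)."""
    n_vals = set(np.unique(matrix.n)) - {0}
    if n_vals <= {2}:
        per_cell = 2
    elif n_vals <= {1}:
        per_cell = 1
    else:
        raise ValueError(
            "on-disk coding supports uniform haploid or diploid sampling; "
            f"got per-species copy numbers {sorted(n_vals)}"
        )
    lines = [
        "#NEXUS",
        "begin data;",
        f"    dimensions ntax={len(matrix.species)} nchar={matrix.m};",
        '    format datatype=standard symbols="012" missing=?;',
        "    matrix",
    ]
    width = max(len(s) for s in matrix.species) + 2
    for j, sp in enumerate(matrix.species):
        cells = []
        for i in range(matrix.m):
            if matrix.n[i, j] == 0:
                cells.append("?")
            else:
                cells.append(str(int(matrix.r[i, j])))
        lines.append(f"    {sp:<{width}}{''.join(cells)}")
    lines.append("    ;")
    lines.append("end;")
    Path(path).write_text("\n".join(lines) + "\n")


def nucleotide_to_biallelic(
    sequences: Mapping[str, str],
    species_map: Mapping[str, str] | None = None,
) -> tuple[BiallelicMatrix, int]:
    """Recode a nucleotide alignment to biallelic characters.

    Sites with more than two observed nucleotide states are removed and
    counted.  At the remaining sites the first-observed state (in label
    order) is coded green and the other red -- an arbitrary choice that
    is inconsequential under equal stationary frequencies.  Gaps and
    ambiguity codes become missing data.
    """
    labels = sorted(sequences)
    if not labels:
        raise ValueError("empty alignment")
    lengths = {len(sequences[lab]) for lab in labels}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal lengths")
    m = lengths.pop()
    species_of = dict(species_map) if species_map else {lab: lab for lab in labels}
    species = tuple(sorted(set(species_of.values())))
    col = {s: i for i, s in enumerate(species)}

    n_rows, r_rows = [], []
    n_removed = 0
    for i in range(m):
        column = [(lab, sequences[lab][i].upper()) for lab in labels]
        states = [b for _, b in column if b in "ACGT"]
        uniq = []
        for b in states:
            if b not in uniq:
                uniq.append(b)
        if len(uniq) > 2:
            n_removed += 1
            continue
        n = np.zeros(len(species), dtype=np.int64)
        r = np.zeros(len(species), dtype=np.int64)
        for lab, b in column:
            if b not in "ACGT":
                continue
            j = col[species_of[lab]]
            n[j] += 1
            r[j] += int(b != uniq[0]) if uniq else 0
        if n.sum() == 0:
            n_removed += 1
            continue
        n_rows.append(n)
        r_rows.append(r)
    matrix = BiallelicMatrix(species, np.array(n_rows), np.array(r_rows))
    return matrix, n_removed


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


def _dist_from_dict(d: Mapping) -> GammaDist | ExponentialDist:
    kind = d.get("distribution", "gamma")
    if kind == "gamma":
        return GammaDist(shape=float(d["shape"]), mean=float(d["mean"]))
    if kind == "exponential":
        return ExponentialDist(mean=float(d["mean"]))
    raise ValueError(f"unknown distribution {kind!r}")


def prior_config_from_dict(d: Mapping) -> PriorConfig:
    kwargs = {}
    if "root_age" in d:
        kwargs["root_age"] = _dist_from_dict(d["root_age"])
    if "alpha_tau" in d:
        kwargs["alpha_tau"] = float(d["alpha_tau"])
    if "pop_size" in d:
        kwargs["ne"] = _dist_from_dict(d["pop_size"])
    if "pi" in d:
        kwargs["pi"] = float(d["pi"])
    if "mu" in d:
        kwargs["mu"] = float(d["mu"])
    return PriorConfig(**kwargs)


@dataclass
class RunConfig:
    """Everything one inference run needs, loadable from YAML."""

    data_path: str
    prior: PriorConfig = field(default_factory=PriorConfig)
    chains: int = 4
    generations: int = 15_000
    sample_freq: int = 10
    seed: int = 1
    model: str = "MG"
    variable_only: bool = False
    output_dir: str = "genphy-output"
    move_weights: dict[str, float] | None = None

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.generations < self.sample_freq:
            raise ValueError("generations must be >= sample_freq")
        if self.model not in ("MG", "MIB"):
            raise ValueError("model must be MG or MIB")


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    prior = prior_config_from_dict(raw.get("prior", {}))
    return RunConfig(
        data_path=raw["data"],
        prior=prior,
        chains=int(raw.get("chains", 4)),
        generations=int(raw.get("generations", 15_000)),
        sample_freq=int(raw.get("sample_freq", 10)),
        seed=int(raw.get("seed", 1)),
        model=str(raw.get("model", "MG")),
        variable_only=bool(raw.get("variable_only", False)),
        output_dir=str(raw.get("output_dir", "genphy-output")),
        move_weights=raw.get("move_weights"),
    )


# ---------------------------------------------------------------------------
# chain logs
# ---------------------------------------------------------------------------

_STATE_COLUMNS = (
    "generation",
    "ln_likelihood",
    "ln_prior",
    "root_height",
    "tree_length",
    "ne_mu",
    "n_heights",
)


def write_state_log(trace: Trace, path: str | Path) -> None:
    lines = [
        f"# seed={trace.seed} chain={trace.chain_id} "
        f"generations={trace.generations} sample_freq={trace.sample_freq}",
        "\t".join(_STATE_COLUMNS),
    ]
    for s in trace.samples:
        lines.append(
            "\t".join(
                [
                    str(s.generation),
                    f"{s.log_lik:.10g}",
                    f"{s.log_prior:.10g}",
                    f"{s.tree.root_height:.12g}",
                    f"{s.tree.tree_length():.12g}",
                    f"{s.ne_mu:.12g}",
                    str(s.tree.n_classes),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_state_log(path: str | Path) -> dict[str, np.ndarray]:
    rows = []
    header = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        if header is None:
            header = line.split("\t")
            continue
        rows.append([float(x) for x in line.split("\t")])
    if header is None:
        raise ValueError(f"empty state log {path}")
    arr = np.array(rows)
    return {name: arr[:, i] for i, name in enumerate(header)}


def write_tree_log(trace: Trace, path: str | Path) -> None:
    """NEXUS trees block, one annotated tree per sample."""
    if not trace.samples:
        raise ValueError("empty trace")
    taxa = trace.samples[0].tree.tip_labels
    lines = [
        "#NEXUS",
        "begin taxa;",
        f"    dimensions ntax={len(taxa)};",
        "    taxlabels",
    ]
    lines += [f"        {t}" for t in taxa]
    lines += ["    ;", "end;", "begin trees;"]
    for s in trace.samples:
        lines.append(f"    tree gen_{s.generation} = [&R] {s.tree.newick()}")
    lines += ["end;"]
    Path(path).write_text("\n".join(lines) + "\n")


def read_tree_log(path: str | Path) -> list[GeneralizedTree]:
    trees = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line.lower().startswith("tree "):
            continue
        _, _, newick = line.partition("=")
        newick = newick.strip()
        if newick.startswith("[&R]"):
            newick = newick[4:].strip()
        trees.append(parse_tree(newick))
    if not trees:
        raise ValueError(f"no trees found in {path}")
    return trees
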