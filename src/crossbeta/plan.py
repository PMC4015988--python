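"""The study design and reference outcomes, as machine-readable metadata.

The simulation campaign this package reanalyses covers three GNNQQNY point
mutants (N2D, N2S, N6D), four single-sheet sizes (5–8 peptides), two
temperatures (300 and 330 K) and two termini protonation states, with one
extra re-seeded replicate each for 6N2D*/300 K and 7N2S*/330 K — fifty runs
in total. Simulations are named ``nXpY`` (n = peptides per sheet, XpY the
mutation) with a ``*`` suffix for neutral termini.

The per-system stability verdicts and key events of the original campaign
are shipped as a plain-text table (``data/reference_outcomes.csv``);
selected stable systems carry flags for 100 ns extensions, re-seeded
re-initiations, and the single late (~95 ns) dissociation among those.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "MUTANTS",
    "SimulationSpec",
    "PaperOutcome",
    "AgreementReport",
    "simulation_name",
    "enumerate_plan",
    "load_reference_outcomes",
    "compare_to_reference",
]

#: mutant label -> peptide sequence
MUTANTS = {"N2D": "GDNQQNY", "N2S": "GSNQQNY", "N6D": "GNNQQDY"}

SIZES = (5, 6, 7, 8)
TEMPERATURES = (300, 330)
TERMINI = ("charged", "neutral")

#: (name, temperature) of the runs extended to 100 ns
EXTENDED_RUNS = frozenset(
    [("6N2D*", 300), ("8N2S*", 300), ("5N6D*", 300),
     ("5N2S*", 330), ("7N2S*", 330), ("7N6D*", 330)]
)
#: (name, temperature) of the runs re-initiated with a fresh seed
REINITIATED_RUNS = frozenset([("6N2D*", 300), ("7N2S*", 330)])

VERDICTS = ("stable", "unstable")
KEY_EVENTS = ("none", "disorder", "dissociation", "disintegration", "rearrangement", "collapse")
FOOTNOTES = ("extended", "reinitiated", "late_instability")


class PlanError(ValueError):
    """Invalid simulation spec or malformed reference metadata."""


@dataclass(frozen=True)
class SimulationSpec:
    mutant_label: str
    n_peptides: int
    temperature: int  # K
    termini: str
    replicate: int = 1
    duration_ns: int = 50
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.mutant_label not in MUTANTS:
            raise PlanError(f"unknown mutant label {self.mutant_label!r}")
        if self.n_peptides not in SIZES:
            raise PlanError(f"n_peptides must be one of {SIZES}")
        if self.temperature not in TEMPERATURES:
            raise PlanError(f"temperature must be one of {TEMPERATURES}")
        if self.termini not in TERMINI:
            raise PlanError(f"termini must be one of {TERMINI}")
        if self.replicate < 1:
            raise PlanError("replicate must be >= 1")
        bad = set(self.flags) - set(FOOTNOTES[:2])
        if bad:
            raise PlanError(f"unknown flags {sorted(bad)}")

    @property
    def name(self) -> str:
        return simulation_name(self)

    @property
    def sequence(self) -> str:
        return MUTANTS[self.mutant_label]


@dataclass(frozen=True)
class PaperOutcome:
    name: str
    temperature: int
    verdict: str
    key_event: str
    footnotes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise PlanError(f"{self.name}/{self.temperature}: bad verdict {self.verdict!r}")
        if self.key_event not in KEY_EVENTS:
            raise PlanError(f"{self.name}/{self.temperature}: bad key event {self.key_event!r}")
        if self.verdict == "stable" and self.key_event != "none":
            raise PlanError(f"{self.name}/{self.temperature}: stable systems carry no key event")
        if self.verdict == "unstable" and self.key_event == "none":
            raise PlanError(f"{self.name}/{self.temperature}: unstable systems need a key event")
        bad = set(self.footnotes) - set(FOOTNOTES)
        if bad:
            raise PlanError(f"{self.name}/{self.temperature}: unknown footnotes {sorted(bad)}")

    @property
    def termini(self) -> str:
        return "neutral" if self.name.endswith("*") else "charged"


def simulation_name(spec: SimulationSpec) -> str:
    """nXpY naming scheme; '*' appended for neutral termini."""
    star = "*" if spec.termini == "neutral" else ""
    return f"{spec.n_peptides}{spec.mutant_label}{star}"


def enumerate_plan() -> list[SimulationSpec]:
    """The full 50-run campaign, in deterministic
    (mutant, size, temperature, termini, replicate) order."""
    plan: list[SimulationSpec] = []
    for mutant in MUTANTS:
        for n in SIZES:
            for temp in TEMPERATURES:
                for termini in TERMINI:
                    star = "*" if termini == "neutral" else ""
                    key = (f"{n}{mutant}{star}", temp)
                    flags = set()
                    if key in EXTENDED_RUNS:
                        flags.add("extended")
                    duration = 100 if "extended" in flags else 50
                    plan.append(SimulationSpec(mutant, n, temp, termini, 1, duration,
                                               frozenset(flags)))
                    if key in REINITIATED_RUNS:
                        plan.append(SimulationSpec(mutant, n, temp, termini, 2, 50,
                                                   frozenset({"reinitiated"})))
    return plan


def load_reference_outcomes() -> list[PaperOutcome]:
    """The 48 per-system reference verdicts shipped with the package."""
    out: list[PaperOutcome] = []
    text = resources.files("crossbeta").joinpath("data/reference_outcomes.csv").read_text()
    reader = csv.DictReader(text.splitlines())
    for i, row in enumerate(reader, start=2):
        try:
            fns = frozenset(f for f in (row["footnotes"] or "").split(";") if f)
            out.append(PaperOutcome(
                name=row["name"].strip(),
                temperature=int(row["temperature"]),
                verdict=row["verdict"].strip(),
                key_event=row["key_event"].strip(),
                footnotes=fns,
            ))
        except (KeyError, ValueError, PlanError) as exc:
            raise PlanError(f"reference_outcomes.csv line {i} ({row.get('name')}): {exc}") from exc
    seen = {(o.name, o.temperature) for o in out}
    if len(seen) != len(out):
        raise PlanError("duplicate (name, temperature) entries in reference outcomes")
    return out


@dataclass(frozen=True)
class AgreementReport:
    rows: tuple  # (name, temperature, verdict_match, key_event_match)
    agreement: float | None  # fraction of systems with matching verdicts

    @property
    def n(self) -> int:
        return len(self.rows)


def compare_to_reference(verdicts, outcomes: list[PaperOutcome]) -> AgreementReport:
    """Match computed verdicts against reference outcomes.

    ``verdicts`` is an iterable of (name, temperature, verdict, key_event)
    tuples; key_event may be None for stable systems. Raises on a name that
    has no reference entry.
    """
    ref = {(o.name, o.temperature): o for o in outcomes}
    rows = []
    n_match = 0
    for name, temp, verdict, key_event in verdicts:
        if (name, temp) not in ref:
            raise KeyError(f"no reference outcome for {name}/{temp} K")
        o = ref[(name, temp)]
        v_match = verdict == o.verdict
        k_match = (key_event or "none") == o.key_event
        n_match += v_match
        rows.append((name, temp, v_match, k_match))
    agreement = n_match / len(rows) if rows else None
    return AgreementReport(rows=tuple(rows), agreement=agreement)
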