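"""Synthetic study generator: cohorts, note texts and labeled corpora.

Real H&P corpora with chart-review labels are private, so every
experiment here runs on synthetic data with known ground truth.  The
generator mirrors the analysis model exactly: covariates are drawn from
configured marginals, each patient gets a normal random intercept, each
encounter another, and each note's "contains a negatively-used
descriptor" indicator is Bernoulli with logit equal to the linear
predictor plus both intercepts.  Note *text* is then rendered from a
template bank whose sentences are rule-consistent with their intended
context label, so on noise-free data the detection pipeline recovers
the generating indicators exactly and parameter recovery is a
well-posed experiment.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .classify import (
    CONTEXT_LABELS,
    NEGATIVE,
    OUT_OF_CONTEXT,
    POSITIVE,
    LabeledSentence,
    classify_rule_based,
)
from .cohort import (
    ADJUSTED_TERMS,
    EncounterRecord,
    PatientRecord,
    code_covariates,
)
from .lexicon import Descriptor, build_default_lexicon, match_descriptors
from .preprocess import NoteDocument

__all__ = [
    "SimConfig",
    "default_config",
    "TemplateBank",
    "default_template_bank",
    "generate_cohort",
    "render_notes",
    "generate_labeled_corpus",
    "inject_missingness",
]


@dataclass
class SimConfig:
    """Generating parameters for a synthetic study.

    Defaults (see ``data/sim_defaults.yaml``) encode the emulated study
    conditions: covariate marginals, ~1.8 encounters and ~2.2 notes per
    patient, conditional log-odds effects equal to the natural logs of
    the adjusted odds ratios being recovered, nested random-intercept
    variances, and a baseline intercept calibrated so that roughly 8.2%
    of patients end up with at least one negative note.
    """

    n_patients: int
    covariate_marginals: dict
    encounter: dict
    true_beta: dict
    sigma2_patient: float
    sigma2_encounter: float
    baseline_intercept: float
    distractor_positive_rate: float
    distractor_ooc_rate: float
    missing_race: int
    missing_covariates: int
    noise_token_dropout: float
    seed: int = 0

    def __post_init__(self) -> None:
        for name, table in self.covariate_marginals.items():
            probs = np.asarray(list(table.values()), dtype=float)
            if (probs < 0).any() or (probs > 1).any():
                raise ValueError(f"covariate {name}: probabilities outside [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-6:
                raise ValueError(f"covariate {name}: probabilities sum to {probs.sum():.6f}, not 1")
        if self.sigma2_patient < 0 or self.sigma2_encounter < 0:
            raise ValueError("random-intercept variances must be non-negative")


def default_config(**overrides) -> SimConfig:
    """Load the version-controlled default configuration, optionally
    overriding individual fields."""
    source = resources.files("notelex").joinpath("data/sim_defaults.yaml")
    raw = yaml.safe_load(source.read_text())
    raw.update(overrides)
    return SimConfig(**raw)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


def _draw(rng: np.random.Generator, table: dict, n: int) -> np.ndarray:
    keys = np.asarray(list(table.keys()), dtype=object)
    probs = np.asarray(list(table.values()), dtype=float)
    probs = probs / probs.sum()
    return rng.choice(keys, size=n, p=probs)


def generate_cohort(
    config: SimConfig,
) -> tuple[list[PatientRecord], list[EncounterRecord], pd.DataFrame]:
    """Draw a synthetic patient/encounter/note hierarchy.

    Returns ``(patients, encounters, skeletons)`` where ``skeletons``
    has one row per note with its ids, the true per-note probability of
    a negative descriptor and the realized binary indicator.  Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cm = config.covariate_marginals
    enc_cfg = config.encounter

    race = _draw(rng, cm["race"], n)
    age = _draw(rng, cm["age_band"], n)
    sex = _draw(rng, cm["sex"], n)
    married = _draw(rng, cm["married"], n) == "married"
    english = _draw(rng, cm["english_primary"], n) == "english"
    insurance = _draw(rng, cm["insurance"], n)
    covid = _draw(rng, cm["covid_positive"], n) == "positive"

    patients: list[PatientRecord] = []
    encounters: list[EncounterRecord] = []
    skeleton_rows: list[dict] = []
    beta = dict(config.true_beta)
    sd_p = math.sqrt(config.sigma2_patient)
    sd_e = math.sqrt(config.sigma2_encounter)

    for i in range(n):
        pid = f"P{i:06d}"
        patient = PatientRecord(
            patient_id=pid,
            race_ethnicity=str(race[i]),
            age_band=str(age[i]),
            sex=str(sex[i]),
            insurance=str(insurance[i]),
            married=bool(married[i]),
            english_primary=bool(english[i]),
            covid_positive=bool(covid[i]),
        )
        patients.append(patient)
        u = rng.normal(0.0, sd_p)
        n_enc = 1 + rng.poisson(enc_cfg["encounters_per_patient_lambda"])
        for j in range(n_enc):
            eid = f"{pid}-E{j:02d}"
            encounter = EncounterRecord(
                encounter_id=eid,
                patient_id=pid,
                location=str(_draw(rng, enc_cfg["location"], 1)[0]),
                length_days=float(rng.exponential(enc_cfg["length_days_mean"])),
                cci=float(rng.poisson(enc_cfg["cci_mean"])),
                after_cutoff=bool(rng.random() < enc_cfg["after_cutoff_prob"]),
            )
            encounters.append(encounter)
            w = rng.normal(0.0, sd_e)
            row = code_covariates(patient, encounter)
            lin = config.baseline_intercept + sum(
                beta.get(term, 0.0) * value for term, value in row.items()
            )
            n_notes = 1 + rng.poisson(enc_cfg["notes_per_encounter_lambda"])
            for k in range(n_notes):
                prob = float(expit(lin + u + w))
                skeleton_rows.append(
                    {
                        "note_id": f"{eid}-N{k:02d}",
                        "encounter_id": eid,
                        "patient_id": pid,
                        "true_prob": prob,
                        "true_negative": int(rng.random() < prob),
                    }
                )
    return patients, encounters, pd.DataFrame(skeleton_rows)


def inject_missingness(
    registry: Sequence[PatientRecord],
    n_missing_race: int,
    n_missing_covariates: int,
    seed: int = 0,
) -> list[PatientRecord]:
    """Blank fields in disjoint random subsets of the registry.

    Exactly ``n_missing_race`` patients lose race/ethnicity and a
    further disjoint ``n_missing_covariates`` lose one model covariate
    (explicit ``None`` sentinels, never silent imputation).
    """
    if n_missing_race + n_missing_covariates > len(registry):
        raise ValueError("missingness counts exceed registry size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(registry))
    race_set = set(order[:n_missing_race].tolist())
    cov_set = set(order[n_missing_race : n_missing_race + n_missing_covariates].tolist())
    out: list[PatientRecord] = []
    covariate_fields = ("age_band", "sex", "insurance", "married", "english_primary")
    for i, p in enumerate(registry):
        if i in race_set:
            out.append(replace(p, race_ethnicity=None))
        elif i in cov_set:
            fld = covariate_fields[int(rng.integers(len(covariate_fields)))]
            out.append(replace(p, **{fld: None}))
        else:
            out.append(replace(p))
    return out


# --------------------------------------------------------------------------
# template bank and note rendering
# --------------------------------------------------------------------------

#: Interchangeable clinical filler phrases substituted for "{F}".
FILLERS = (
    "this morning",
    "overnight",
    "at bedside",
    "during rounds",
    "earlier today",
    "on repeat evaluation",
    "per nursing report",
    "throughout the shift",
)

#: Neutral padding sentences containing no descriptor stem.
NEUTRAL_SENTENCES = (
    "Vital signs stable.",
    "Lungs clear to auscultation bilaterally.",
    "Abdomen soft and nontender.",
    "Patient resting comfortably in bed.",
    "Labs reviewed and discussed with the team.",
    "Plan to continue current management.",
    "No acute distress observed.",
    "Follow up scheduled with primary care.",
    "Heart regular rate and rhythm.",
    "Tolerating a regular diet.",
)

# Primary adjectival/participial surface form per descriptor term.
_SURFACE = {
    "adherent": "adherent",
    "aggressive": "aggressive",
    "agitated": "agitated",
    "angry": "angry",
    "challenging": "challenging",
    "combative": "combative",
    "compliant": "compliant",
    "confront": "confrontational",
    "cooperative": "cooperative",
    "defensive": "defensive",
    "exaggerate": "exaggerating",
    "hysterical": "hysterical",
    "pleasant": "pleasant",
    "refuse": "refusing",
    "resist": "resisting",
}

# Noun forms adding variety to positive templates of the four
# polarity-by-negation descriptors.
_NOUN = {"adherent": "adherence", "compliant": "compliance", "cooperative": "cooperation"}


@dataclass
class TemplateBank:
    """Sentence templates per (descriptor term, context label).

    Templates contain a ``{F}`` slot for a filler phrase; every
    instantiated template must contain exactly one lexicon hit and be
    labeled by the rule classifier as the intended label (validated by
    :meth:`validate`).
    """

    templates: dict[tuple[str, str], tuple[str, ...]]

    def get(self, term: str, label: str) -> tuple[str, ...]:
        try:
            return self.templates[(term, label)]
        except KeyError:
            raise KeyError(f"template bank has no cell for ({term!r}, {label!r})") from None

    def instantiate(self, term: str, label: str, rng: np.random.Generator) -> str:
        template = self.get(term, label)[int(rng.integers(len(self.get(term, label))))]
        return template.replace("{F}", FILLERS[int(rng.integers(len(FILLERS)))])

    def validate(self, lexicon: list[Descriptor] | None = None) -> None:
        lexicon = lexicon or build_default_lexicon()
        for (term, label), templates in self.templates.items():
            for template in templates:
                text = template.replace("{F}", FILLERS[0])
                hits = match_descriptors(text, lexicon)
                if len({h.descriptor.term for h in hits}) != 1:
                    raise ValueError(f"template for ({term}, {label}) has != 1 descriptor: {text!r}")
                got = classify_rule_based(text, hits)
                if got != label:
                    raise ValueError(
                        f"template for ({term}, {label}) is rule-inconsistent "
                        f"(classified {got}): {text!r}"
                    )


def default_template_bank() -> TemplateBank:
    """Build and validate the default 15 × 3 template bank."""
    templates: dict[tuple[str, str], tuple[str, ...]] = {}
    lexicon = build_default_lexicon()
    for desc in lexicon:
        a = _SURFACE[desc.term]
        if desc.polarity_class == "inherent_negative":
            neg = (
                f"Patient was {a} {{F}}.",
                f"He became {a} when asked about his medications.",
                f"She remained {a} {{F}} despite redirection.",
            )
            pos = (
                f"Patient denies being {a} {{F}}.",
                f"He denied feeling {a} during the interview.",
            )
            ooc = (
                f"The {a} valve was noted on imaging {{F}}.",
                f"Wound dressing was {a} and intact {{F}}.",
            )
            if desc.term == "resist":
                ooc = (
                    "Blood cultures grew vancomycin resistant organisms {F}.",
                    "The wound grew multi-drug resistant bacteria {F}.",
                )
        else:
            neg = (
                f"Patient has been poorly {a} with medications {{F}}.",
                f"She is non-{a} with the treatment plan.",
                f"He was not {a} {{F}}.",
            )
            pos = (
                f"Patient has been {a} with medications {{F}}.",
                f"She is calm and {a} with the interview.",
            )
            if desc.term in _NOUN:
                pos = pos + (f"Patient reports {_NOUN[desc.term]} with home medications.",)
            if desc.term == "pleasant":
                neg = neg + ("Patient was unpleasant and rude with staff {F}.",)
                pos = pos + ("Patient is pleasant and conversant {F}.",)
            ooc = (
                f"A non-{a} balloon was used during the procedure.",
                f"A non-{a} bandage was applied to the site {{F}}.",
            )
        templates[(desc.term, NEGATIVE)] = neg
        templates[(desc.term, POSITIVE)] = pos
        templates[(desc.term, OUT_OF_CONTEXT)] = ooc
    bank = TemplateBank(templates)
    bank.validate(lexicon)
    return bank


def render_notes(
    skeletons: pd.DataFrame,
    template_bank: TemplateBank | None = None,
    lexicon: list[Descriptor] | None = None,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> list[NoteDocument]:
    """Realize note text for every skeleton row.

    Notes whose true indicator is 1 contain at least one
    negative-template sentence; positive and out-of-context distractor
    sentences are injected at the configured rates into any note;
    neutral filler sentences pad every note.
    """
    config = config or default_config()
    bank = template_bank or default_template_bank()
    lexicon = lexicon or build_default_lexicon()
    terms = [d.term for d in lexicon]
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)

    notes: list[NoteDocument] = []
    for row in skeletons.itertuples(index=False):
        sentences = [
            NEUTRAL_SENTENCES[int(rng.integers(len(NEUTRAL_SENTENCES)))]
            for _ in range(2 + int(rng.integers(3)))
        ]
        if row.true_negative:
            term = terms[int(rng.integers(len(terms)))]
            sentences.append(bank.instantiate(term, NEGATIVE, rng))
        if rng.random() < config.distractor_positive_rate:
            term = terms[int(rng.integers(len(terms)))]
            sentences.append(bank.instantiate(term, POSITIVE, rng))
        if rng.random() < config.distractor_ooc_rate:
            term = terms[int(rng.integers(len(terms)))]
            sentences.append(bank.instantiate(term, OUT_OF_CONTEXT, rng))
        order = rng.permutation(len(sentences))
        notes.append(
            NoteDocument(
                note_id=row.note_id,
                encounter_id=row.encounter_id,
                patient_id=row.patient_id,
                text=" ".join(sentences[i] for i in order),
                note_time="2020-06-01T00:00:00",
            )
        )
    return notes


# --------------------------------------------------------------------------
# labeled corpus generation
# --------------------------------------------------------------------------

# Tokens that carry the label signal; never dropped by lexical noise.
_PROTECTED = {
    "non", "not", "poorly", "never", "no", "longer", "denies", "denied", "without",
    "balloon", "bandage", "dressing", "airway", "organism", "organisms", "bacteria",
    "tourniquet", "valve", "catheter", "methicillin", "vancomycin", "drug", "multi",
    "antibiotic", "mrsa", "vre",
}


def _apply_noise(text: str, rng: np.random.Generator, dropout: float, stems: list[str]) -> str:
    if dropout <= 0:
        return text
    words = text.split()
    kept = []
    for word in words:
        bare = word.lower().strip(".,;:")
        protected = bare in _PROTECTED or any(stem in bare for stem in stems)
        if protected or rng.random() >= dropout:
            kept.append(word)
    if not kept:
        return text
    out = " ".join(kept)
    if not out.endswith("."):
        out += "."
    return out


def generate_labeled_corpus(
    n_sentences: int,
    class_mix: Sequence[float] = (0.35, 0.45, 0.20),
    template_bank: TemplateBank | None = None,
    seed: int = 0,
    noise_token_dropout: float = 0.05,
) -> list[LabeledSentence]:
    """Draw a labeled sentence corpus from the template bank.

    ``class_mix`` gives the (negative, positive, out_of_context)
    proportions and must sum to 1; counts are assigned by largest
    remainder so exactly ``n_sentences`` are produced.  Lexical noise
    (filler variation plus low-rate dropout of non-signal tokens) makes
    the classification task non-trivial; labels always come from the
    generating template.
    """
    mix = np.asarray(class_mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    bank = template_bank or default_template_bank()
    lexicon = build_default_lexicon()
    stems = [d.stem for d in lexicon]
    terms = [d.term for d in lexicon]
    rng = np.random.default_rng(seed)

    raw = mix * n_sentences
    counts = np.floor(raw).astype(int)
    remainder = n_sentences - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i % 3]] += 1

    corpus: list[LabeledSentence] = []
    for label, count in zip(CONTEXT_LABELS, counts):
        for _ in range(int(count)):
            term = terms[int(rng.integers(len(terms)))]
            text = bank.instantiate(term, label, rng)
            text = _apply_noise(text, rng, noise_token_dropout, stems)
            hits = match_descriptors(text, lexicon)
            if not hits:  # dropout never removes the descriptor, but be safe
                text = bank.instantiate(term, label, rng)
                hits = match_descriptors(text, lexicon)
            corpus.append(LabeledSentence(text=text, hits=tuple(hits), label=label))
    perm = rng.permutation(len(corpus))
    return [corpus[i] for i in perm]
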