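"""p-values -> categorical eye / hair / skin phenotype calls.

Eye colour is plain argmax over its three probabilities.  Hair (8
categories) combines the hair-colour argmax with dark-shade thresholds, and
skin (12 categories) refines the 5-way base tone with lighter/darker
modifiers.  Exact probability ties resolve to the darker category, and the
skin modifiers are computed from the *tail mass* lying strictly darker or
strictly lighter than the base tone — both choices encode the scheme's
darker-tone precedence and make the classification monotone under
darkening.

The decision rules are data: a versioned YAML rules file supplies category
orders, thresholds and display labels, so users holding the official manual
can transcribe its exact decision tree without code changes.  The shipped
default rules file is an explicit approximation of that manual.  Every call
records a ``rule_trace`` naming the rules that fired, which is what makes
misclassification post-mortems (e.g. a false-red case) auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .model import GROUPS, ModelCoefficients, PValueVector, read_pvalue_csv
from .translate import NA_TOKEN, SAMPLE_COLUMN

__all__ = [
    "RuleSet",
    "PhenotypeCall",
    "RulesError",
    "ClassificationError",
    "DialectError",
    "HAIR_UNAVAILABLE",
    "UNDEFINED",
    "load_rules",
    "classify_eye",
    "classify_hair",
    "classify_skin",
    "classify_all",
    "write_phenotype_tsv",
    "WEB_DIALECT_COLUMNS",
]

HAIR_UNAVAILABLE = "unavailable"
UNDEFINED = "undefined"

#: threshold rank used when picking the strongest satisfied shade modifier
_THRESHOLD_ORDER = ("black", "strong", "mild")


class RulesError(ValueError):
    """Rules file is malformed or not total over the probability simplex."""


class ClassificationError(ValueError):
    """A required trait group is undefined for this sample."""


class DialectError(ValueError):
    """p-value table header matches neither the native nor the web dialect."""


@dataclass(frozen=True)
class RuleSet:
    version: str
    eye_order: tuple           # model categories, light -> dark
    eye_labels: dict
    hair_order: tuple          # hair-colour categories, light -> dark
    hair_red: str
    hair_shade_dark: str       # the hair_shade category meaning "dark"
    hair_thresholds: dict      # {"mild": t, "strong": t, "black": t}
    hair_labels: dict          # colour -> {"base"/"mild"/"strong"/"black" -> label} | label
    skin_order: tuple          # skin categories, light -> dark
    skin_darker_tail: float
    skin_lighter_tail: float
    skin_labels: dict          # base -> {"lighter"/"base"/"darker" -> label}


@dataclass
class PhenotypeCall:
    sample_id: str
    eye: str
    hair: str
    skin: str
    rule_trace: list = field(default_factory=list)


def load_rules(path) -> RuleSet:
    """Load a rules YAML and verify it is total at classification time."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        eye = raw["eye"]
        hair = raw["hair"]
        skin = raw["skin"]
        rules = RuleSet(
            version=str(raw.get("version", "unversioned")),
            eye_order=tuple(eye["order_light_to_dark"]),
            eye_labels=dict(eye.get("labels") or {}),
            hair_order=tuple(hair["order_light_to_dark"]),
            hair_red=hair["red_category"],
            hair_shade_dark=hair["shade_dark_category"],
            hair_thresholds={k: float(v) for k, v in hair["thresholds"].items()},
            hair_labels=dict(hair["labels"]),
            skin_order=tuple(skin["order_light_to_dark"]),
            skin_darker_tail=float(skin["darker_tail_threshold"]),
            skin_lighter_tail=float(skin["lighter_tail_threshold"]),
            skin_labels={k: dict(v) for k, v in skin["labels"].items()},
        )
    except (KeyError, TypeError) as exc:
        raise RulesError(f"{path}: missing or malformed rules entry: {exc}") from exc

    # totality checks: every category must resolve to a label for every
    # threshold outcome, so no probability vector can fall through at runtime
    if rules.hair_red not in rules.hair_order:
        raise RulesError(f"red category {rules.hair_red!r} not in hair order")
    for colour in rules.hair_order:
        spec = rules.hair_labels.get(colour)
        if spec is None:
            raise RulesError(f"hair colour {colour!r} has no label mapping")
        if isinstance(spec, dict) and "base" not in spec:
            raise RulesError(f"hair colour {colour!r} lacks a base label")
    for name in rules.hair_thresholds:
        if name not in _THRESHOLD_ORDER:
            raise RulesError(f"unknown hair shade threshold {name!r}")
    for base in rules.skin_order:
        spec = rules.skin_labels.get(base)
        if not spec or "base" not in spec:
            raise RulesError(f"skin tone {base!r} lacks a base label")
    if not 0.0 < rules.skin_darker_tail <= 1.0 or not 0.0 < rules.skin_lighter_tail <= 1.0:
        raise RulesError("skin tail thresholds must lie in (0, 1]")
    return rules


def _argmax_darker(probs: dict, order: tuple) -> str:
    """Argmax with exact ties resolved to the darker (later-in-order) category."""
    best, best_p = None, -1.0
    for cat in order:  # light -> dark; >= keeps the darker of tied categories
        if probs[cat] >= best_p:
            best, best_p = cat, probs[cat]
    return best


def classify_eye(pv: PValueVector, rules: RuleSet):
    """Most likely eye colour: argmax of the three eye probabilities."""
    probs = pv.probs.get("eye")
    if probs is None:
        raise ClassificationError("eye group undefined for this sample")
    cat = _argmax_darker(probs, rules.eye_order)
    label = rules.eye_labels.get(cat, cat)
    return label, [f"eye:argmax={cat}"]


def classify_hair(pv: PValueVector, rules: RuleSet):
    """Hair category from colour argmax + dark-shade thresholds; red first."""
    if not pv.hair_prediction_available:
        return HAIR_UNAVAILABLE, ["hair:mc1r_all_missing"]
    colour_probs = pv.probs.get("hair_colour")
    if colour_probs is None:
        raise ClassificationError("hair colour group undefined for this sample")
    max_p = max(colour_probs.values())
    if colour_probs[rules.hair_red] >= max_p:  # red precedence on ties
        return _hair_label(rules, rules.hair_red, None), ["hair:red"]
    base = _argmax_darker(
        {c: p for c, p in colour_probs.items() if c != rules.hair_red},
        tuple(c for c in rules.hair_order if c != rules.hair_red),
    )
    trace = [f"hair:base={base}"]
    shade_probs = pv.probs.get("hair_shade")
    if shade_probs is None:
        trace.append("hair:shade_undefined")
        return _hair_label(rules, base, None), trace
    d = shade_probs[rules.hair_shade_dark]
    spec = rules.hair_labels[base]
    modifier = None
    if isinstance(spec, dict):
        for name in _THRESHOLD_ORDER:
            if name in spec and name in rules.hair_thresholds and d >= rules.hair_thresholds[name]:
                modifier = name
                break
    if modifier:
        trace.append(f"hair:shade_dark={d:.3f}>={modifier}")
    return _hair_label(rules, base, modifier), trace


def _hair_label(rules: RuleSet, colour: str, modifier):
    spec = rules.hair_labels[colour]
    if not isinstance(spec, dict):
        return spec
    return spec.get(modifier or "base", spec["base"])


def classify_skin(pv: PValueVector, rules: RuleSet):
    """Base tone by argmax, lighter/darker modifier by tail mass.

    The darker tail always contains the darkest category, so adding mass to
    it can only darken the call (darker-tone precedence).
    """
    probs = pv.probs.get("skin")
    if probs is None:
        raise ClassificationError("skin group undefined for this sample")
    base = _argmax_darker(probs, rules.skin_order)
    idx = rules.skin_order.index(base)
    darker_tail = sum(probs[c] for c in rules.skin_order[idx + 1:])
    lighter_tail = sum(probs[c] for c in rules.skin_order[:idx])
    spec = rules.skin_labels[base]
    trace = [f"skin:base={base}"]
    if "darker" in spec and darker_tail >= rules.skin_darker_tail:
        trace.append(f"skin:darker_tail={darker_tail:.3f}>={rules.skin_darker_tail}")
        return spec["darker"], trace
    if "lighter" in spec and lighter_tail >= rules.skin_lighter_tail:
        trace.append(f"skin:lighter_tail={lighter_tail:.3f}>={rules.skin_lighter_tail}")
        return spec["lighter"], trace
    return spec["base"], trace


def classify_sample(sample_id: str, pv: PValueVector, rules: RuleSet) -> PhenotypeCall:
    trace = []
    try:
        eye, t = classify_eye(pv, rules)
        trace += t
    except ClassificationError:
        eye = UNDEFINED
        trace.append("eye:undefined")
    hair, t = classify_hair(pv, rules)
    trace += t
    try:
        skin, t = classify_skin(pv, rules)
        trace += t
    except ClassificationError:
        skin = UNDEFINED
        trace.append("skin:undefined")
    return PhenotypeCall(sample_id, eye, hair, skin, trace)


# --- web-tool download dialect ----------------------------------------------

#: batch-result column -> (group, model category); assumed spelling, see docs
WEB_DIALECT_COLUMNS = {
    "PBlueEye": ("eye", 0), "PIntermediateEye": ("eye", 1), "PBrownEye": ("eye", 2),
    "PBlondHair": ("hair_colour", 0), "PBrownHair": ("hair_colour", 1),
    "PRedHair": ("hair_colour", 2), "PBlackHair": ("hair_colour", 3),
    "PLightHair": ("hair_shade", 0), "PDarkHair": ("hair_shade", 1),
    "PVeryPaleSkin": ("skin", 0), "PPaleSkin": ("skin", 1),
    "PIntermediateSkin": ("skin", 2), "PDarkSkin": ("skin", 3),
    "PDarkBlackSkin": ("skin", 4),
}


def _read_web_dialect(path, model: ModelCoefficients):
    df = pd.read_csv(path)
    missing = ({"sampleid"} | set(WEB_DIALECT_COLUMNS)) - set(df.columns)
    if missing:
        raise DialectError(
            f"{path}: not a recognised p-value table; missing columns {sorted(missing)}"
        )
    results = []
    for _, rec in df.iterrows():
        probs = {g: {} for g in GROUPS}
        undefined = {g: True for g in GROUPS}
        for col, (gname, cat_idx) in WEB_DIALECT_COLUMNS.items():
            cat = model.groups[gname].categories[cat_idx]
            value = rec[col]
            if pd.isna(value):
                probs[gname][cat] = None
            else:
                probs[gname][cat] = float(value)
                undefined[gname] = False
        clean = {g: (None if undefined[g] else probs[g]) for g in GROUPS}
        hair_ok = clean["hair_colour"] is not None
        pv = PValueVector(probs=clean, n_missing_markers=0,
                          hair_prediction_available=hair_ok)
        results.append((str(rec["sampleid"]), pv))
    return results


def classify_all(pvalues, rules: RuleSet, model: ModelCoefficients = None,
                 dialect: str = "auto"):
    """Classify a p-value table (path or ``(sample, PValueVector)`` pairs).

    File input accepts the package's native dialect or the web tool's batch
    download dialect (``dialect`` one of auto/native/web).  Returns one
    :class:`PhenotypeCall` per sample, rule traces included.
    """
    if isinstance(pvalues, (str, bytes)) or hasattr(pvalues, "__fspath__"):
        if model is None:
            raise ValueError("classifying from a file requires the model (for category names)")
        if dialect == "native":
            results = read_pvalue_csv(pvalues, model)
        elif dialect == "web":
            results = _read_web_dialect(pvalues, model)
        else:
            with open(pvalues) as fh:
                header = fh.readline().strip().split(",")
            if SAMPLE_COLUMN in header and any(c.startswith("p_eye_") for c in header):
                results = read_pvalue_csv(pvalues, model)
            elif set(WEB_DIALECT_COLUMNS) <= set(header):
                results = _read_web_dialect(pvalues, model)
            else:
                raise DialectError(
                    f"{pvalues}: header matches neither the native dialect "
                    f"(sampleid, p_<group>_<category>...) nor the web dialect "
                    f"({sorted(WEB_DIALECT_COLUMNS)})"
                )
    else:
        results = list(pvalues)
    return [classify_sample(sid, pv, rules) for sid, pv in results]


def write_phenotype_tsv(calls, path) -> None:
    df = pd.DataFrame(
        {
            SAMPLE_COLUMN: [c.sample_id for c in calls],
            "eye": [c.eye for c in calls],
            "hair": [c.hair for c in calls],
            "skin": [c.skin for c in calls],
            "rule_trace": [";".join(c.rule_trace) for c in calls],
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)
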