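"""End-to-end pipeline: read, infer demographics, filter, score, report.

``run`` executes the analysis half of the study design: corpus in, one
report bundle out. Per demographic attribute it writes distinctive terms,
distinctive disorders, distinctive drugs, a sentiment table, and an
emotion table with group-vs-rest significance markers, plus a run manifest
(config hash, seed, stage counts) that makes the run reproducible. All
output ordering is deterministic, so identical config + seed reproduces
byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import concepts as concepts_mod
from . import corpus as corpus_mod
from . import demographics as demo_mod
from . import distinctive as dist_mod
from . import lexicon as lex_mod
from . import relevance as rel_mod
from . import textproc

log = logging.getLogger(__name__)

_PKG_DATA = Path(__file__).parent / "data"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    corpus: Path
    sentiment_lexicon: Path
    emotion_lexicon: Path
    concepts: Path = _PKG_DATA / "concepts.tsv"
    users: Path | None = None
    blacklist: Path | None = _PKG_DATA / "blacklist.tsv"
    keywords: Path | None = _PKG_DATA / "keywords.tsv"
    stopwords: Path | None = None
    names_first: Path | None = _PKG_DATA / "names_first.tsv"
    names_last: Path | None = _PKG_DATA / "names_last.tsv"
    display_allow: Path | None = None
    display_block: Path | None = None
    attributes: tuple[str, ...] = ("gender",)
    k: int = 10
    min_reldif: float = 0.1
    gender_dominance: float = demo_mod.GENDER_DOMINANCE
    ethnicity_dominance: float = demo_mod.ETHNICITY_DOMINANCE
    alpha: float = 0.05
    seed: int = 0
    filtered_sources: tuple[str, ...] = ("social_network",)
    out: Path = Path("reports")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def _p(key, default=None):
            if key not in raw or raw[key] is None:
                return default
            return (base / raw[key]).resolve()

        kwargs: dict = {}
        for key in ("corpus", "sentiment_lexicon", "emotion_lexicon"):
            val = _p(key)
            if val is None:
                raise PipelineError("config", f"{path}: missing required path {key!r}")
            kwargs[key] = val
        for key, default in (("concepts", cls.concepts), ("users", None),
                             ("blacklist", cls.blacklist), ("keywords", cls.keywords),
                             ("stopwords", None), ("names_first", cls.names_first),
                             ("names_last", cls.names_last),
                             ("display_allow", None), ("display_block", None)):
            kwargs[key] = _p(key, default)
        if "attributes" in raw:
            kwargs["attributes"] = tuple(raw["attributes"])
        for key in ("k", "min_reldif", "gender_dominance", "ethnicity_dominance",
                    "alpha", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "filtered_sources" in raw:
            kwargs["filtered_sources"] = tuple(raw["filtered_sources"])
        kwargs["out"] = _p("out", (base / "reports").resolve())
        return cls(**kwargs)

    def validate(self) -> None:
        for key in ("corpus", "sentiment_lexicon", "emotion_lexicon", "concepts",
                    "users", "blacklist", "keywords", "stopwords", "names_first",
                    "names_last", "display_allow", "display_block"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise PipelineError("config", f"{key} path does not exist: {val}")
        for attr in self.attributes:
            if attr not in corpus_mod.ATTRIBUTES:
                raise PipelineError("config", f"unknown attribute {attr!r}")

    def content_hash(self) -> str:
        """Digest of the analysis inputs: parameter values plus the *content*
        of every referenced input file (not its location), so relocated but
        identical inputs hash the same. 'out' is where results land, not
        what they are, and is excluded."""
        record: dict[str, str] = {}
        for key, val in self.__dict__.items():
            if key == "out":
                continue
            if isinstance(val, Path):
                h = hashlib.sha256()
                with open(val, "rb") as fh:
                    for chunk in iter(lambda: fh.read(1 << 16), b""):
                        h.update(chunk)
                record[key] = h.hexdigest()
            else:
                record[key] = str(val)
        blob = json.dumps(record, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_wordlist(path) -> frozenset[str]:
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip().lower()
            if line and not line.startswith("#"):
                out.add(line)
    return frozenset(out)


def infer_missing_demographics(profiles: Mapping[str, corpus_mod.UserProfile],
                               posts_by_user: Mapping[str, list[str]],
                               first_table: demo_mod.NameTable | None,
                               last_table: demo_mod.NameTable | None,
                               gender_dominance: float,
                               ethnicity_dominance: float,
                               ) -> dict[str, corpus_mod.UserProfile]:
    """Fill gender/ethnicity from names and writing level from post texts."""
    out = {}
    for uid, prof in profiles.items():
        updates: dict = {}
        if prof.gender is None and first_table is not None:
            g = demo_mod.classify_gender(prof.first_name, first_table,
                                         gender_dominance)
            if g is not None:
                updates["gender"] = g
        if prof.ethnicity is None and last_table is not None:
            e = demo_mod.classify_ethnicity(prof.last_name, last_table,
                                            ethnicity_dominance)
            if e is not None:
                updates["ethnicity"] = e
        if prof.writing_level_grade is None:
            wl = demo_mod.user_writing_level(posts_by_user.get(uid, ()))
            if wl is not None:
                updates["writing_level_grade"] = wl.grade
        out[uid] = prof.with_classified(**updates) if updates else prof
    return out


def _write_ranked(path: Path, attribute: str,
                  ranked: Mapping[str, list[dist_mod.RankedItem]],
                  surface_example) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group\trank\titem\tsurface_example\tfreq\tavg_freq\treldif\n")
        for group in sorted(ranked):
            rows = ranked[group]
            if not rows:
                fh.write(f"{group}\t-\tN/A\t-\t-\t-\t-\n")
                continue
            for r in rows:
                fh.write(f"{group}\t{r.rank}\t{r.item}\t{surface_example(r.item)}"
                         f"\t{r.freq:.6f}\t{r.avg_freq:.6f}\t{r.reldif:.4f}\n")


def report_emotion_table(group_scores: Mapping[str, lex_mod.GroupScore],
                         emotions: Sequence[str] = lex_mod.REPORTED_EMOTIONS,
                         ) -> str:
    """Render the per-group emotion table; '*' marks P <= alpha vs the rest."""
    lines = ["group\tn_scored\t" + "\t".join(f"{e} (%)" for e in emotions)]
    for group in sorted(group_scores):
        gs = group_scores[group]
        cells = []
        for e in emotions:
            stat = gs.emotions[e]
            mark = "*" if stat.significant else ""
            cells.append(f"{stat.percent:.1f}{mark}")
        lines.append(f"{group}\t{gs.n_scored}\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def report_sentiment_table(group_scores: Mapping[str, lex_mod.GroupScore]) -> str:
    lines = ["group\tn_posts\tn_scored\tpositive\tnegative\tobjective"
             "\tp_positive\tp_negative\tp_objective"]
    for group in sorted(group_scores):
        gs = group_scores[group]
        lines.append(f"{group}\t{gs.n_posts}\t{gs.n_scored}"
                     f"\t{gs.positive:.6f}\t{gs.negative:.6f}\t{gs.objective:.6f}"
                     f"\t{gs.sentiment_p['positive']:.4g}"
                     f"\t{gs.sentiment_p['negative']:.4g}"
                     f"\t{gs.sentiment_p['objective']:.4g}")
    return "\n".join(lines) + "\n"


@dataclass
class RunResult:
    outdir: Path
    counts: dict = field(default_factory=dict)
    files: list[str] = field(default_factory=list)


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis pipeline; see module docstring."""
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    # -- stage: read ----------------------------------------------------------
    try:
        posts, profiles = corpus_mod.read_corpus(config.corpus, config.users)
    except corpus_mod.CorpusError as exc:
        raise PipelineError("read", str(exc)) from exc
    counts["posts_read"] = len(posts)
    counts["users_read"] = len(profiles)

    # -- stage: demographics --------------------------------------------------
    try:
        first_table = (demo_mod.load_name_table(config.names_first, corpus_mod.GENDERS)
                       if config.names_first else None)
        last_table = (demo_mod.load_name_table(config.names_last,
                                               corpus_mod.ETHNICITIES)
                      if config.names_last else None)
        posts_by_user: dict[str, list[str]] = {}
        for p in posts:
            posts_by_user.setdefault(p.user_id, []).append(p.text)
        profiles = infer_missing_demographics(
            profiles, posts_by_user, first_table, last_table,
            config.gender_dominance, config.ethnicity_dominance)
    except demo_mod.NameTableError as exc:
        raise PipelineError("demographics", str(exc)) from exc

    # -- stage: relevance filter ----------------------------------------------
    if config.keywords is not None and config.filtered_sources:
        try:
            keywords = rel_mod.load_keywords(config.keywords)
            posts, kw_counts = rel_mod.filter_corpus(posts, keywords,
                                                     config.filtered_sources)
        except rel_mod.KeywordError as exc:
            raise PipelineError("relevance", str(exc)) from exc
        with open(outdir / "keyword_counts.tsv", "w", encoding="utf-8") as fh:
            fh.write("keyword\tmatched_posts\n")
            for kw in sorted(kw_counts):
                fh.write(f"{kw}\t{kw_counts[kw]}\n")
    counts["posts_after_filter"] = len(posts)

    # -- stage: load lexicons / dictionary ------------------------------------
    try:
        slex = lex_mod.load_sentiment_lexicon(config.sentiment_lexicon)
        elex = lex_mod.load_emotion_lexicon(config.emotion_lexicon)
    except lex_mod.LexiconError as exc:
        raise PipelineError("lexicons", str(exc)) from exc
    try:
        dictionary = concepts_mod.load_dictionary(config.concepts)
        blacklist = (concepts_mod.load_blacklist(config.blacklist)
                     if config.blacklist else frozenset())
    except concepts_mod.DictionaryError as exc:
        raise PipelineError("concepts", str(exc)) from exc
    stopwords = (textproc.load_stopwords(config.stopwords)
                 if config.stopwords else textproc.default_stopwords())

    # -- stage: per-post processing -------------------------------------------
    scores: dict[str, lex_mod.PostScore] = {}
    term_items: dict[str, list[str]] = {}
    surface_counts: dict[str, Counter] = {}
    disorder_items: dict[str, list[str]] = {}
    drug_items: dict[str, list[str]] = {}
    concept_names: dict[str, str] = {}
    n_scored = 0
    n_annotated = 0
    for post in posts:
        tokens = textproc.pos_tag(textproc.normalize(post.text, stopwords))
        scores[post.post_id] = lex_mod.score_tokens(tokens, slex, elex)
        if scores[post.post_id].sentiment.scored:
            n_scored += 1
        stems = []
        for t in tokens:
            if not t.is_stopword:
                stems.append(t.stem)
                surface_counts.setdefault(t.stem, Counter())[t.surface.lower()] += 1
        term_items[post.post_id] = stems
        anns = concepts_mod.annotate_tokens(tokens, dictionary, blacklist)
        if anns:
            n_annotated += 1
        disorder_items[post.post_id] = [a.concept_id for a in anns
                                        if a.semantic_group == "Disorders"]
        drug_items[post.post_id] = [a.concept_id for a in anns
                                    if a.semantic_group == "Chemicals & Drugs"]
        for a in anns:
            concept_names[a.concept_id] = dictionary.entries[a.concept_id].preferred_name
    counts["posts_scored"] = n_scored
    counts["posts_with_concepts"] = n_annotated

    allow = _load_wordlist(config.display_allow) if config.display_allow else None
    block = _load_wordlist(config.display_block) if config.display_block else frozenset()

    def term_surface(stem: str) -> str:
        c = surface_counts.get(stem)
        return c.most_common(1)[0][0] if c else stem

    def concept_surface(cid: str) -> str:
        return concept_names.get(cid, cid)

    # -- stage: per-attribute analysis ----------------------------------------
    files: list[str] = []
    for attribute in config.attributes:
        partition = corpus_mod.partition_posts(posts, profiles, attribute)
        counts[f"posts_annotated_{attribute}"] = sum(map(len, partition.values()))
        if len([g for g, ps in partition.items() if ps]) < 2:
            log.warning("attribute %r has <2 non-empty groups; skipped", attribute)
            continue
        for name, items, surface in (
                ("terms", term_items, term_surface),
                ("disorders", disorder_items, concept_surface),
                ("drugs", drug_items, concept_surface)):
            try:
                _, _, top = dist_mod.distinctive_items(
                    partition, lambda p, it=items: it[p.post_id],
                    attribute=attribute, k=config.k, min_reldif=config.min_reldif,
                    allow=allow if name == "terms" else None,
                    block=block if name == "terms" else frozenset())
            except dist_mod.AnalysisError as exc:
                raise PipelineError(f"distinctive:{attribute}:{name}", str(exc)) from exc
            fname = f"{name}_{attribute}.tsv"
            _write_ranked(outdir / fname, attribute, top, surface)
            files.append(fname)

        grouped_scores = {g: [scores[p.post_id] for p in ps]
                          for g, ps in partition.items()}
        group_scores = lex_mod.aggregate_groups(grouped_scores, alpha=config.alpha)
        for fname, text in ((f"sentiment_{attribute}.tsv",
                             report_sentiment_table(group_scores)),
                            (f"emotions_{attribute}.tsv",
                             report_emotion_table(group_scores))):
            (outdir / fname).write_text(text, encoding="utf-8")
            files.append(fname)

    # -- stage: manifest ------------------------------------------------------
    manifest = {"config_hash": config.content_hash(), "seed": config.seed,
                "counts": counts, "files": sorted(files)}
    with open(outdir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("stage counts: %s", counts)
    return RunResult(outdir=outdir, counts=counts, files=sorted(files))
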