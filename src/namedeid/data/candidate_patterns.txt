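# Context regexes for selecting annotation candidates (one per line,
# Python re syntax; '#' lines are comments).  Used to enrich a corpus with
# narratives likely to contain names before manual annotation.
(?i)\b(?:dr|doctor|mr|mrs|ms|miss|prof|professor|sister|nurse)\b[.\s]
(?i)\b(?:name|patient|reporter|consultant|gp)\s*:
(?i)\b(?:md|m\.d\.|phd|rn|frcp)\b
\b[A-Z]\.?\s?[A-Z]\b(?![A-Za-z])
(?i)\b(?:regards|signed|yours sincerely|best wishes)\b
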