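# Drug lexicon for the five orally administered dopamine agonists.
# Generic and trade names are matched exactly (case-insensitive);
# misspelling_variants is a curated list of close misspellings seen in
# verbatim drug fields, backed up at match time by an edit-distance
# fallback against the generic/trade names.  Editable without code changes.
bromocriptine:
  generic_names: [bromocriptine, bromocriptine mesylate]
  trade_names: [parlodel, cycloset]
  misspelling_variants: [bromocryptine, bromocriptin, bromocriptene, bromocriptime]
cabergoline:
  generic_names: [cabergoline]
  trade_names: [dostinex, cabaser]
  misspelling_variants: [cabergolin, carbergoline, cabergiline]
pergolide:
  generic_names: [pergolide, pergolide mesylate]
  trade_names: [permax]
  misspelling_variants: [pergolid, pergolide mesilate, pergalide]
pramipexole:
  generic_names: [pramipexole, pramipexole dihydrochloride]
  trade_names: [mirapex, mirapexin, sifrol]
  misspelling_variants: [pramipexol, pramiprexole, praminpexole, pramipexole hcl]
ropinirole:
  generic_names: [ropinirole, ropinirole hydrochloride]
  trade_names: [requip]
  misspelling_variants: [ropinerole, ropinrole, ropirinole, ropinirol]
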