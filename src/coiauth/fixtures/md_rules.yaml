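# Trade-name rules for the Italian sushi survey.
# Each row maps a normalized menu/trade name to one taxon it lawfully declares;
# duplicate trade names merge by union.  "listed: false" marks names that the
# survey tables footnote as absent from the Italian ministerial decree list
# (they are still evaluated).  Sources: MD n.19105 22/09/2017 name list and the
# sushi trade usage recorded in the survey tables.
- {trade_name: tuna, rank: species, taxon: Thunnus thynnus, listed: true, source: "MD n.19105 22/09/2017"}
- {trade_name: red tuna, rank: species, taxon: Thunnus thynnus, listed: true, source: "MD n.19105 22/09/2017"}
- {trade_name: maguro, rank: species, taxon: Thunnus thynnus, listed: false, source: "sushi trade usage"}
- {trade_name: yellowfin tuna, rank: species, taxon: Thunnus albacares, listed: true, source: "MD n.19105 22/09/2017"}
- {trade_name: bigeye tuna, rank: species, taxon: Thunnus obesus, listed: true, source: "MD n.19105 22/09/2017"}
- {trade_name: orientalis tuna, rank: species, taxon: Thunnus orientalis, listed: true, source: "MD n.19105 22/09/2017"}
- {trade_name: oceanic tuna, rank: species, taxon: Thunnus orientalis, listed: true, source: "MD n.19105 22/09/2017"}
- {trade_name: sea bream, rank: species, taxon: Sparus aurata, listed: true, source: "MD n.19105 22/09/2017"}
- {trade_name: common bass, rank: species, taxon: Dicentrarchus labrax, listed: true, source: "MD n.19105 22/09/2017"}
- {trade_name: tobiko, rank: genus, taxon: Hirundichthys, listed: false, source: "sushi trade usage (flying-fish roe)"}
- {trade_name: tobiko, rank: genus, taxon: Cheilopogon, listed: false, source: "sushi trade usage (flying-fish roe)"}
- {trade_name: flying fish egg, rank: genus, taxon: Hirundichthys, listed: false, source: "sushi trade usage (flying-fish roe)"}
- {trade_name: flying fish egg, rank: genus, taxon: Cheilopogon, listed: false, source: "sushi trade usage (flying-fish roe)"}
- {trade_name: flying fish roe, rank: genus, taxon: Hirundichthys, listed: false, source: "sushi trade usage (flying-fish roe)"}
- {trade_name: flying fish roe, rank: genus, taxon: Cheilopogon, listed: false, source: "sushi trade usage (flying-fish roe)"}
- {trade_name: ikura, rank: genus, taxon: Oncorhynchus, listed: false, source: "sushi trade usage (salmon roe)"}
- {trade_name: salmon eggs, rank: genus, taxon: Oncorhynchus, listed: true, source: "MD n.19105 22/09/2017 (salmon)"}
- {trade_name: lumpfish roe, rank: species, taxon: Cyclopterus lumpus, listed: true, source: "MD n.19105 22/09/2017"}
- {trade_name: anago, rank: genus, taxon: Anguilla, listed: false, source: "sushi trade usage (eel)"}
- {trade_name: kajiki, rank: species, taxon: Xiphias gladius, listed: false, source: "sushi trade usage (swordfish)"}
- {trade_name: swordfish, rank: species, taxon: Xiphias gladius, listed: true, source: "MD n.19105 22/09/2017"}
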