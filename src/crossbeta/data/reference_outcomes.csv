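name,temperature,verdict,key_event,footnotes
5N2D,300,unstable,collapse,
6N2D,300,unstable,dissociation,
7N2D,300,unstable,dissociation,
8N2D,300,unstable,dissociation,
5N2S,300,unstable,disintegration,
6N2S,300,unstable,dissociation,
7N2S,300,unstable,dissociation,
8N2S,300,unstable,disintegration,
5N6D,300,unstable,dissociation,
6N6D,300,unstable,disintegration,
7N6D,300,unstable,disintegration,
8N6D,300,unstable,disintegration,
5N2D*,300,unstable,dissociation,
6N2D*,300,stable,none,extended;reinitiated
7N2D*,300,stable,none,
8N2D*,300,unstable,dissociation,
5N2S*,300,stable,none,
6N2S*,300,stable,none,
7N2S*,300,stable,none,
8N2S*,300,stable,none,extended
5N6D*,300,stable,none,extended
6N6D*,300,stable,none,
7N6D*,300,stable,none,
8N6D*,300,stable,none,
5N2D,330,unstable,disintegration,
6N2D,330,unstable,dissociation,
7N2D,330,unstable,disintegration,
8N2D,330,unstable,dissociation,
5N2S,330,unstable,dissociation,
6N2S,330,unstable,disintegration,
7N2S,330,unstable,disintegration,
8N2S,330,unstable,disintegration,
5N6D,330,unstable,dissociation,
6N6D,330,unstable,disintegration,
7N6D,330,unstable,disintegration,
8N6D,330,unstable,disintegration,
5N2D*,330,unstable,disorder,
6N2D*,330,unstable,dissociation,
7N2D*,330,unstable,dissociation,
8N2D*,330,unstable,dissociation,
5N2S*,330,stable,none,extended;late_instability
6N2S*,330,stable,none,
7N2S*,330,stable,none,extended;reinitiated
8N2S*,330,stable,none,
5N6D*,330,unstable,rearrangement,
6N6D*,330,unstable,disintegration,
7N6D*,330,stable,none,extended
8N6D*,330,unstable,dissociation,
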