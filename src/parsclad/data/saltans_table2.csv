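#taxon,Fused Ventral Parameres,Middle Ventral Process,Scales in the Middle Ventral Process,Punctiform Projection in the Aedeagus Apex,Ventral Parameres of Epandrium,Concave Surstylus,Apical Crest of Aedeagus,Apical Crest with Punctiform Projection,Groove in the Apical Crest,Bristles in the Aedeagus Apical Crest,Scales in the Aedeagus Apical Crest,Aedeagus Cape,Serrated Edge of Aedeagus Cape,Dorsal Cleft of Aedeagus,Frontal Processes of Aedeagus,Bipartite Aedeagus Apex,Surstylus Processes,Sickle-Shaped Processes of Aedeagus,Long Apodeme
willistoni,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
prosaltans,0,0,0,0,0,1,1,0,0,0,1,1,1,0,1,0,0,0,1
lusaltans,0,0,0,0,0,1,1,0,1,0,1,1,1,0,0,0,0,0,1
saltans,0,0,0,0,0,1,1,0,0,1,0,1,2,0,1,0,0,0,1
austrosaltans,0,0,0,0,0,1,1,1,0,0,1,1,1,0,1,0,0,0,1
sturtevanti,1,1,0,1,1,0,0,0,0,0,0,0,0,0,1,0,0,0,0
dacunhai,1,1,1,1,1,0,0,0,0,0,0,0,0,0,1,0,0,0,0
milleri,1,1,1,1,1,0,0,0,0,0,0,0,0,0,1,0,0,0,0
parasaltans,0,0,0,0,2,0,0,0,0,0,0,1,1,0,1,0,0,0,1
neocordata,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1,1,0
emarginata,1,0,0,0,0,1,0,0,0,0,0,0,0,1,1,1,0,0,0
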