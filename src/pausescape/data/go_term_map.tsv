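set_name	go_id	go_name
Chromatin	GO:0051276	chromosome organization
Chromatin	GO:0006325	chromatin organization
Chromatin	GO:0006338	chromatin remodeling
Initiation	GO:0051123	RNA polymerase II preinitiation complex assembly
Initiation	GO:0006367	transcription initiation from RNA polymerase II promoter
Elongation	GO:0006368	transcription elongation from RNA polymerase II promoter
Termination	GO:0006369	termination of RNA polymerase II transcription
Splicing	GO:0045292	mRNA splicing via spliceosome
Splicing	GO:0000381	regulation of alternative mRNA splicing via spliceosome
Processing	GO:0006406	mRNA export from nucleus
Processing	GO:0031124	mRNA 3'-end processing
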