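extractor,original,gwo1,gwo2
alexnet-like,4096,2248,1478
inception-like,2048,1476,683
mobilenet-like,1280,923,333
resnet-like,2048,1420,776
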