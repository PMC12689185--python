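code,description,mets
02015,"bicycling, stationary, high-intensity interval session",11.0
02040,"bicycling, stationary, vigorous effort",7.5
02050,"resistance training, circuit, vigorous effort",6.0
02052,"resistance training, multiple exercises, moderate-to-vigorous effort",5.0
02054,"resistance training, light or moderate effort",3.5
02160,"mind-body conditioning, dynamic flow practice",4.0
15670,"tai chi, general",3.3
15674,"qigong/yoga, vigorous flowing style",6.0
17346,"walking, 2.5 mph, level, firm surface",2.8
17358,"walking, 3.5 mph, level, brisk",4.8
17364,"walking, 4.5 mph, level, very brisk",6.8
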