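state,prevalence_pct,se_pct,published_rank
Alabama,16.7,0.9,5
Alaska,10.7,0.8,36
Arizona,12.1,0.8,27
Arkansas,16.2,1.0,7
California,6.5,1.3,46
Colorado,14.4,1.5,14
Connecticut,12.2,0.8,26
Delaware,12.2,0.6,27
Florida,10.4,0.4,37
Georgia,13.7,1.0,18
Hawaii,9.4,0.5,42
Idaho,10.7,0.6,36
Illinois,12.2,0.7,26
Indiana,13.3,1.0,20
Iowa,16.3,1.5,6
Kansas,11.6,0.7,31
Kentucky,18.5,1.0,2
Louisiana,14.8,1.2,12
Maine,11.6,0.4,30
Maryland,10.0,0.6,40
Massachusetts,9.9,0.5,40
Michigan,10.8,0.7,35
Mississippi,15.8,0.9,8
Missouri,11.4,0.9,32
Montana,13.7,0.6,18
Nebraska,12.5,0.7,25
Nevada,7.9,0.6,44
New Hampshire,13.4,0.8,20
New Jersey,12.7,1.0,24
New Mexico,14.4,0.7,14
New York,9.6,0.5,41
North Carolina,13.8,0.7,17
North Dakota,15.0,0.7,11
Ohio,16.5,1.6,6
Oklahoma,16.1,1.0,7
Pennsylvania,11.3,1.3,32
Rhode Island,7.6,0.7,45
South Carolina,13.9,0.9,17
South Dakota,14.2,1.4,15
Tennessee,15.0,0.8,11
Texas,13.9,0.7,17
Utah,4.7,0.4,47
Vermont,11.3,0.5,32
Virginia,10.3,0.8,38
West Virginia,18.4,0.8,2
Wisconsin,11.8,0.7,29
Wyoming,17.1,0.8,4
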